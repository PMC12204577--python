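"""Download-free synthetic test data with known generative ground truth.

This module fabricates IEDB-style exports — peptides in the ``SEQ +
MOD(XN)`` notation, 9/10-mer lengths, IC50 labels — whose labels come from a
known latent-linear model of token chemistry, so the full pipeline
(ingest -> tokenize -> featurize -> encode -> regress) can be exercised as a
parameter-recovery experiment without any external download.

Generative model
----------------
Peptide composition is driven by ``latent_rank`` peptide-level factors
``z ~ N(0, I)``: the residue at each position is the canonical token whose
standardized embedding coordinates lie nearest to a factor-determined
target, emulating the position-spanning physicochemical preferences (anchor
residues) of a real MHC binding groove.  The log10 IC50 is then an exact
linear function of the peptide's chemistry encoding, with coefficients
supported on the ``latent_rank`` realized composition-factor directions,
plus Gaussian noise:

    log10 IC50 = b0 + w . encode(peptide) + N(0, noise_sd)

Because the factors make embedding coordinates covary across positions with
a distinct strength per factor, a PLS regressor needs about ``latent_rank``
components to capture the signal, so the component scan recovers the
planted rank (a statistical property of the draw, not a certainty at every
seed).  Observed IC50 is clipped to the assay-plausible range
0.1–65,000 nM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import encoder, featurizer, tokenizer
from .registry import ChemRegistry, TokenChemEntry, builtin_canonical, write_registry

logger = logging.getLogger(__name__)

FIXTURE_HLA = "HLA-A*02:01"
FIXTURE_RESPONSE = "IC50 nM"
IC50_MIN_NM = 0.1
IC50_MAX_NM = 65000.0

#: Pool of chemically sensible free-amino-acid variants for demo registries:
#: (residue letter, modification method code, SMILES, display name).
NCAA_POOL: tuple[tuple[str, str, str, str], ...] = (
    ("A", "MET", "CC(C)(N)C(=O)O", "2-aminoisobutyric acid"),
    ("A", "HAL", "NC(CCl)C(=O)O", "3-chloroalanine"),
    ("S", "PHO", "N[C@@H](COP(=O)(O)O)C(=O)O", "phosphoserine"),
    ("Y", "PHO", "N[C@@H](Cc1ccc(OP(=O)(O)O)cc1)C(=O)O", "phosphotyrosine"),
    ("K", "ACE", "CC(=O)NCCCC[C@H](N)C(=O)O", "N6-acetyllysine"),
    ("K", "MET", "CNCCCC[C@H](N)C(=O)O", "N6-methyllysine"),
    ("R", "MET", "CNC(=N)NCCC[C@H](N)C(=O)O", "N-methylarginine"),
    ("F", "HAL", "N[C@@H](Cc1ccc(F)cc1)C(=O)O", "4-fluorophenylalanine"),
    ("F", "OTH", "N[C@@H](CCc1ccccc1)C(=O)O", "homophenylalanine"),
    ("V", "OTH", "CCC[C@H](N)C(=O)O", "norvaline"),
    ("L", "OTH", "CCCC[C@H](N)C(=O)O", "norleucine"),
    ("P", "HYX", "O=C(O)[C@@H]1C[C@H](O)CN1", "4-hydroxyproline"),
    ("C", "OXI", "N[C@@H](CS(=O)(=O)O)C(=O)O", "cysteic acid"),
    ("M", "OXI", "CS(=O)CC[C@H](N)C(=O)O", "methionine sulfoxide"),
    ("W", "HAL", "N[C@@H](Cc1c[nH]c2ccc(Br)cc12)C(=O)O", "5-bromotryptophan"),
    ("T", "OTH", "CO[C@@H](C)[C@H](N)C(=O)O", "O-methylthreonine"),
    ("G", "MET", "CNCC(=O)O", "sarcosine"),
    ("D", "MET", "COC(=O)C[C@H](N)C(=O)O", "aspartate 4-methyl ester"),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_peptides: int = 150
    frac_length9: float = 0.6
    n_ncaa_types: int = 8
    mods_per_peptide: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.3}
    )
    latent_rank: int = 3
    noise_sd: float = 0.2  # log10(IC50) units
    seed: int = 0


@dataclass
class FixtureTruth:
    """Ground truth: the planted linear model and the generator's tallies."""

    coefficients: np.ndarray  # (100,), on the encoding scale
    intercept: float
    per_peptide_true_y: np.ndarray
    token_tallies: dict[str, int]
    n_clipped: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.tolist(),
                "intercept": self.intercept,
                "per_peptide_true_y": self.per_peptide_true_y.tolist(),
                "token_tallies": dict(sorted(self.token_tallies.items())),
                "n_clipped": self.n_clipped,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        d = json.loads(text)
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            per_peptide_true_y=np.asarray(d["per_peptide_true_y"], dtype=float),
            token_tallies={k: int(v) for k, v in d["token_tallies"].items()},
            n_clipped=int(d["n_clipped"]),
        )


def generate_registry(
    n_ncaa_types: int, seed: int, path: str | Path | None = None
) -> ChemRegistry:
    """Canonical 20 plus *n_ncaa_types* pool entries sampled without replacement."""
    if n_ncaa_types > len(NCAA_POOL):
        raise ValueError(
            f"n_ncaa_types={n_ncaa_types} exceeds the demo pool size {len(NCAA_POOL)}"
        )
    rng = np.random.default_rng(seed)
    reg = builtin_canonical()
    idx = rng.choice(len(NCAA_POOL), size=n_ncaa_types, replace=False)
    for i in sorted(idx):
        letter, method, smiles, display = NCAA_POOL[i]
        reg.add(
            TokenChemEntry(
                token_id=f"{letter}_{method}",
                smiles=smiles,
                display_name=display,
                source="synthetic-demo-pool",
            )
        )
    if path is not None:
        write_registry(reg, path)
    return reg


def _standardized_coords(vectors: dict[str, np.ndarray], rank: int):
    """Per-dimension standardization of embedding coords over unique tokens."""
    tokens = sorted(vectors)
    V = np.vstack([vectors[t] for t in tokens])
    sd = V[:, :rank].std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    q = {t: vectors[t][:rank] / sd for t in tokens}
    return q, sd


#: factor tilt strengths (geometric decay) and per-position scatter of the
#: residue sampler, in standardized embedding units
TILT_ALPHA0 = 2.4
TILT_DECAY = 0.6
TILT_SIGMA = 0.4


def _sample_peptides(spec: FixtureSpec, registry: ChemRegistry, rng) -> list[tokenizer.TokenizedPeptide]:
    """Draw peptides whose composition covaries with latent chemistry factors.

    Each peptide carries ``latent_rank`` factors ``z ~ N(0, I)``; the residue
    at every position is the canonical token whose standardized embedding
    coordinates are nearest to ``alpha * z`` plus per-position scatter.  This
    makes the same embedding axis covary across positions with a distinct
    strength per factor — the synthetic analogue of anchor-position
    physicochemical preferences.
    """
    canon = sorted(t for t in registry.entries if len(t) == 1)
    ncaa = sorted(t for t in registry.entries if "_" in t)
    # registry-wide embedding map drives the composition tilt
    fmap = featurizer.build_token_map(registry, registry.entries.keys())
    q, _ = _standardized_coords(fmap.vectors, spec.latent_rank)
    Q = np.vstack([q[t] for t in canon])  # (20, rank)
    alpha = TILT_ALPHA0 * TILT_DECAY ** np.arange(spec.latent_rank)

    mod_counts = np.array(sorted(spec.mods_per_peptide))
    mod_probs = np.array([spec.mods_per_peptide[m] for m in mod_counts], dtype=float)
    mod_probs = mod_probs / mod_probs.sum()

    peptides = []
    for _ in range(spec.n_peptides):
        length = 9 if rng.random() < spec.frac_length9 else 10
        z = rng.standard_normal(spec.latent_rank)
        targets = alpha * z + TILT_SIGMA * rng.standard_normal((length, spec.latent_rank))
        nearest = np.argmin(
            ((Q[None, :, :] - targets[:, None, :]) ** 2).sum(axis=2), axis=1
        )
        base = [canon[j] for j in nearest]
        n_mods = int(rng.choice(mod_counts, p=mod_probs)) if ncaa else 0
        n_mods = min(n_mods, len(ncaa), length)
        tags = []
        if n_mods:
            chosen = rng.choice(len(ncaa), size=n_mods, replace=False)
            positions = rng.choice(length, size=n_mods, replace=False)
            for tok_idx, pos in zip(chosen, positions):
                letter, method = ncaa[tok_idx].split("_", 1)
                base[pos] = letter  # the modified residue's parent letter
                tags.append(
                    tokenizer.ModificationTag(
                        method=method, residue_letter=letter, position=int(pos) + 1
                    )
                )
        peptides.append(tokenizer.tokenize("".join(base), tags))
    return peptides


def generate_dataset(
    spec: FixtureSpec,
    registry: ChemRegistry | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, FixtureTruth]:
    """Emit an IEDB-style export table plus its generative ground truth.

    The planted coefficient vector lives on the first ``latent_rank``
    embedding dimensions of every position block, scaled so each latent
    contributes equal variance to log10 IC50 (total signal SD ~ 1 log unit,
    centered near 10^2.2 ~ 160 nM).  Ground-truth responses regenerate
    exactly as ``encodings @ coefficients + intercept`` when the emitted CSV
    is re-processed through the public ingest/tokenize/encode pipeline.
    """
    if registry is None:
        registry = generate_registry(spec.n_ncaa_types, spec.seed)
    rng = np.random.default_rng(spec.seed)
    peptides = _sample_peptides(spec, registry, rng)

    # the definitive token map: fitted on the observed unique tokens, exactly
    # as a pipeline consumer of the emitted CSV would fit it
    observed = sorted({t for p in peptides for t in p.tokens})
    fmap = featurizer.build_token_map(registry, observed)
    X, _ids = encoder.encode_dataset(peptides, fmap)

    # The planted coefficients live on the realized shared-composition
    # factors: the top eigenvectors of the averaged cross-position
    # covariance of the (column-standardized) encodings.  Averaging over
    # position pairs isolates the peptide-level factors from per-position
    # residue idiosyncrasy, so log10 IC50 depends on exactly `latent_rank`
    # directions of encoding space.
    rank = spec.latent_rank
    n_pos = encoder.TARGET_DIM // fmap.n_dims
    d = fmap.n_dims
    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0)
    col_sd = np.where(col_sd < 1e-12, 1.0, col_sd)
    B = ((X - col_mean) / col_sd).reshape(len(X), n_pos, d)
    C = np.zeros((d, d))
    for i in range(n_pos):
        for j in range(n_pos):
            if i != j:
                C += B[:, i, :].T @ B[:, j, :] / len(X)
    C = (C + C.T) / (2 * n_pos * (n_pos - 1))
    evals, evecs = np.linalg.eigh(C)
    V = evecs[:, np.argsort(evals)[::-1][:rank]]  # (d, rank) factor loadings

    scores = B.sum(axis=1) @ V  # (n, rank) per-peptide factor scores
    target_total_sd = 1.0  # log10 units of planted signal
    s_sd = scores.std(axis=0)
    s_sd = np.where(s_sd < 1e-12, 1.0, s_sd)
    c = (target_total_sd / np.sqrt(rank)) / s_sd  # equal variance per factor

    coefficients = np.tile(V @ c, n_pos) / col_sd
    center = 2.2  # mean log10 IC50, ~160 nM
    intercept = center - float(np.mean(X @ coefficients))
    y_true = X @ coefficients + intercept

    y_obs = y_true + rng.normal(0.0, spec.noise_sd, size=len(y_true))
    ic50 = np.power(10.0, y_obs)
    clipped = (ic50 < IC50_MIN_NM) | (ic50 > IC50_MAX_NM)
    ic50 = np.clip(ic50, IC50_MIN_NM, IC50_MAX_NM)
    if clipped.any():
        logger.info("clipped %d/%d labels to [%g, %g] nM", clipped.sum(), len(ic50), IC50_MIN_NM, IC50_MAX_NM)

    table = pd.DataFrame(
        {
            "Name": [p.render_name() for p in peptides],
            "Qualitative Measurement": np.where(ic50 < 500.0, "Positive", "Negative"),
            "Quantitative Measurement": [f"{v:.8g}" for v in ic50],
            "Response Measured": FIXTURE_RESPONSE,
            "HLA": FIXTURE_HLA,
        }
    )
    truth = FixtureTruth(
        coefficients=coefficients,
        intercept=intercept,
        per_peptide_true_y=y_true,
        token_tallies=tokenizer.census(peptides).per_token_counts,
        n_clipped=int(clipped.sum()),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "export.csv", index=False)
        write_registry(registry, out_dir / "registry.tsv")
        (out_dir / "truth.json").write_text(truth.to_json())
    return table, truth
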