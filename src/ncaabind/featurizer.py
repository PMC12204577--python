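"""Descriptor featurization of amino-acid tokens and PCA dimensionality reduction.

Each registry token is converted to a fixed, ordered vector of 208 RDKit 2-D
physicochemical descriptors (molecular weight, partial charges, functional
group counts, topological indices, ...).  The descriptor list is *pinned* in
a shipped manifest rather than taken from whatever the installed engine
exposes, so the 208-length contract survives engine upgrades.

Because many descriptors are strongly correlated and the token population is
small, the 208-dimensional vectors are reduced to 10 principal components
fitted on the unique tokens of a dataset; the resulting token -> 10-vector
map, together with the frozen projection, is the unit of reuse for encoding
peptides.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit.Chem import Descriptors

from .errors import FeaturizationError
from .registry import ChemRegistry, TokenChemEntry

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class DescriptorManifest:
    """Frozen, ordered list of descriptor names plus engine provenance."""

    names: tuple[str, ...]
    engine_version: str

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise FeaturizationError("descriptor manifest contains duplicate names")

    def __len__(self) -> int:
        return len(self.names)


def load_default_manifest() -> DescriptorManifest:
    """The shipped 208-descriptor manifest (RDKit 2-D descriptor catalog)."""
    text = resources.files("ncaabind.data").joinpath("descriptor_manifest.json").read_text()
    data = json.loads(text)
    return DescriptorManifest(names=tuple(data["names"]), engine_version=data["engine_version"])


def _descriptor_functions() -> dict[str, callable]:
    return dict(Descriptors.descList)


@dataclass(frozen=True)
class DescriptorVector:
    """One token's descriptor values, in manifest order, sanitized to finite."""

    token_id: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise FeaturizationError(f"non-finite descriptor values for {self.token_id!r}")


def compute_descriptors(
    entry: TokenChemEntry, manifest: DescriptorManifest | None = None
) -> DescriptorVector:
    """Evaluate every manifest descriptor on the token's free amino acid.

    Non-finite engine outputs (e.g. partial-charge descriptors on molecules
    the charge model cannot handle) are replaced by 0 with a warning naming
    the token and descriptor.
    """
    manifest = manifest or load_default_manifest()
    funcs = _descriptor_functions()
    missing = [n for n in manifest.names if n not in funcs]
    if missing:
        raise FeaturizationError(
            f"descriptor engine lacks manifest descriptors {missing[:5]}"
            f"{'...' if len(missing) > 5 else ''}"
        )
    mol = entry.mol()
    values = np.empty(len(manifest), dtype=float)
    for j, name in enumerate(manifest.names):
        try:
            v = float(funcs[name](mol))
        except Exception as exc:  # engine-level failure on this molecule
            raise FeaturizationError(
                f"descriptor {name!r} failed on token {entry.token_id!r}: {exc}"
            ) from exc
        if not math.isfinite(v):
            logger.warning(
                "token %s: descriptor %s is non-finite, sanitized to 0", entry.token_id, name
            )
            v = 0.0
        values[j] = v
    return DescriptorVector(token_id=entry.token_id, values=values)


@dataclass(frozen=True)
class PCAProjection:
    """A fitted, sign-fixed PCA: x -> components @ ((x - mean) / scale)."""

    mean: np.ndarray
    components: np.ndarray  # (n_components, n_features), rows orthonormal
    explained_variance_ratio: np.ndarray
    n_fit_samples: int
    scale: np.ndarray | None = None  # unit-variance scaling, if used

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        centered = x - self.mean
        if self.scale is not None:
            centered = centered / self.scale
        return centered @ self.components.T

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "n_fit_samples": self.n_fit_samples,
            "scale": None if self.scale is None else self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PCAProjection":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            components=np.asarray(d["components"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            n_fit_samples=int(d["n_fit_samples"]),
            scale=None if d.get("scale") is None else np.asarray(d["scale"], dtype=float),
        )


def fit_projection(
    descriptors: Sequence[DescriptorVector],
    n_components: int = 10,
    scaling: str = "none",
) -> PCAProjection:
    """Fit a centered PCA on one row per (unique) token.

    ``scaling="unit-variance"`` standardizes each descriptor column first
    (zero-variance columns get unit scale).  Component signs are fixed so
    that each component's largest-magnitude loading is positive, making the
    projection deterministic across BLAS backends.
    """
    from sklearn.decomposition import PCA

    X = np.vstack([d.values for d in descriptors])
    if scaling not in ("none", "unit-variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    scale = None
    Xw = X
    if scaling == "unit-variance":
        scale = X.std(axis=0, ddof=1)
        scale = np.where(scale == 0, 1.0, scale)
        Xw = (X - X.mean(axis=0)) / scale + X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xw - Xw.mean(axis=0))
    if rank < n_components:
        raise ValueError(
            f"centered descriptor matrix has rank {rank} < n_components={n_components}; "
            "reduce n_components or add tokens"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(Xw)
    components = pca.components_.copy()
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1
    return PCAProjection(
        mean=X.mean(axis=0),
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        n_fit_samples=X.shape[0],
        scale=scale,
    )


@dataclass
class TokenFeatureMap:
    """token id -> 10-d embedding, carrying the projection that produced it."""

    projection: PCAProjection
    vectors: dict[str, np.ndarray]

    @property
    def n_dims(self) -> int:
        return self.projection.n_components

    def __contains__(self, token_id: str) -> bool:
        return token_id in self.vectors

    def __getitem__(self, token_id: str) -> np.ndarray:
        return self.vectors[token_id]

    def to_json(self) -> str:
        payload = {
            "projection": self.projection.to_dict(),
            "vectors": {t: v.tolist() for t, v in sorted(self.vectors.items())},
        }
        blob = json.dumps(payload, sort_keys=True)
        digest = hashlib.sha256(blob.encode()).hexdigest()
        return json.dumps({"content_sha256": digest, **payload}, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TokenFeatureMap":
        data = json.loads(text)
        return cls(
            projection=PCAProjection.from_dict(data["projection"]),
            vectors={t: np.asarray(v, dtype=float) for t, v in data["vectors"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TokenFeatureMap":
        return cls.from_json(Path(path).read_text())


def build_token_map(
    registry: ChemRegistry,
    tokens: Iterable[str],
    manifest: DescriptorManifest | None = None,
    n_components: int = 10,
    scaling: str = "none",
) -> TokenFeatureMap:
    """Featurize the unique *tokens*, fit the PCA, and store the 10-vectors.

    The PCA fit population is the set of unique tokens — one row per token,
    not per residue occurrence — matching the token->vector map construction.
    """
    manifest = manifest or load_default_manifest()
    unique = sorted(set(tokens))
    descriptors = [compute_descriptors(registry.resolve(t), manifest) for t in unique]
    projection = fit_projection(descriptors, n_components=n_components, scaling=scaling)
    vectors = {
        t: projection.transform(d.values) for t, d in zip(unique, descriptors)
    }
    return TokenFeatureMap(projection=projection, vectors=vectors)
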