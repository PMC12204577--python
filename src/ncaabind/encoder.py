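"""Fixed-length peptide encoding from per-token embeddings.

A peptide's input vector is the N->C concatenation of its tokens' 10-d
embeddings; 9-mers are zero-padded at the C-terminal end to the common
width of 100, so that 9- and 10-mers share one model input space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EncodingError
from .featurizer import TokenFeatureMap
from .tokenizer import TokenizedPeptide

#: model input width: 10 positions x 10 embedding dimensions
TARGET_DIM = 100


@dataclass(frozen=True)
class PeptideEncoding:
    peptide_id: str
    length: int
    vector: np.ndarray  # always TARGET_DIM wide

    def __post_init__(self):
        if self.vector.shape != (TARGET_DIM,):
            raise EncodingError(
                f"{self.peptide_id}: encoding width {self.vector.shape} != ({TARGET_DIM},)"
            )


def encode_peptide(peptide: TokenizedPeptide, fmap: TokenFeatureMap) -> PeptideEncoding:
    """Concatenate token embeddings N->C and zero-pad to ``TARGET_DIM``.

    Position ``i`` (1-based) occupies entries ``10*(i-1) .. 10*i - 1``.
    A token missing from the map raises :class:`EncodingError` naming the
    token and its position.
    """
    d = fmap.n_dims
    if peptide.length * d > TARGET_DIM:
        raise EncodingError(
            f"peptide length {peptide.length} exceeds the {TARGET_DIM // d}-position frame"
        )
    vector = np.zeros(TARGET_DIM)
    for i, token in enumerate(peptide.tokens):
        if token not in fmap:
            raise EncodingError(
                f"token {token!r} at position {i + 1} of {peptide.render_name()!r} "
                "is not in the token feature map"
            )
        vector[i * d : (i + 1) * d] = fmap[token]
    return PeptideEncoding(
        peptide_id=peptide.render_name(), length=peptide.length, vector=vector
    )


def encode_dataset(
    peptides: Sequence[TokenizedPeptide], fmap: TokenFeatureMap
) -> tuple[np.ndarray, list[str]]:
    """Row-stack individual encodings, preserving input order.

    Per-peptide failures are aggregated into one :class:`EncodingError`
    listing the offending indices.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failures: list[str] = []
    for idx, pep in enumerate(peptides):
        try:
            enc = encode_peptide(pep, fmap)
        except EncodingError as exc:
            failures.append(f"[{idx}] {exc}")
            continue
        rows.append(enc.vector)
        ids.append(enc.peptide_id)
    if failures:
        raise EncodingError("dataset encoding failed:\n" + "\n".join(failures))
    X = np.vstack(rows) if rows else np.empty((0, TARGET_DIM))
    return X, ids


def encodings_to_frame(X: np.ndarray, ids: Sequence[str]) -> pd.DataFrame:
    """CSV-friendly frame: id column plus ``f001..f100``."""
    cols = [f"f{j + 1:03d}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "peptide_id", list(ids))
    return df
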