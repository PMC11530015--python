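"""Multi-label position-specific triad amino-acid propensity (MLPSTAAP) encoding.

A 49-mer window, with the central K removed, is a 48-residue context with 46
overlapping triads (3-residue words).  For each of the 11 categories the
per-position triad frequency matrix ``F_t`` (8000 x 46) is counted, together
with the complement matrix ``FF_t`` counted over the union of the other 10
categories.  The propensity matrix is the difference of the class-averaged
matrices::

    F  = mean_t F_t      FF = mean_t FF_t      F_MLPSTAAP = F - FF

A window is encoded as the 46-vector that reads, for each triad position j,
the propensity entry at (row index of the triad, j).  Triads containing the
padding symbol 'X' are excluded from counts and encode to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .windowing import AMINO_ACIDS, CENTER, N_CATEGORIES, WINDOW_LEN

ALPHABET = AMINO_ACIDS  # "ACDEFGHIKLMNPQRSTVWY", ranks A=0 .. Y=19
N_TRIADS = 20 ** 3  # 8000
CONTEXT_LEN = WINDOW_LEN - 1  # 48
N_FEATURES = CONTEXT_LEN - 2  # 46

_RANK = {aa: i for i, aa in enumerate(ALPHABET)}

#: Sentinel returned by :func:`triad_row_index` for triads containing a
#: letter outside the 20-residue alphabet (e.g. padding 'X').
NO_INDEX = 0


def triad_row_index(triad: str) -> int:
    """1-based propensity-matrix row of a 3-letter triad.

    ``row = rank(a1)*20^2 + rank(a2)*20 + rank(a3) + 1`` with alphabet ranks
    A=0 .. Y=19, so "AGA" -> 101 and "GAT" -> 2017.  Returns :data:`NO_INDEX`
    (0) when any letter is outside the alphabet.
    """
    if len(triad) != 3:
        raise ValueError(f"triad must have 3 letters, got {triad!r}")
    try:
        return _RANK[triad[0]] * 400 + _RANK[triad[1]] * 20 + _RANK[triad[2]] + 1
    except KeyError:
        return NO_INDEX


def context_of(residues: str) -> str:
    """48-residue context of a 49-mer window: both flanks, central K omitted."""
    if len(residues) != WINDOW_LEN:
        raise ValueError(f"window must have {WINDOW_LEN} residues")
    return residues[:CENTER] + residues[CENTER + 1:]


def class_frequency_matrix(contexts: Sequence[str]) -> np.ndarray:
    """Per-position triad frequency matrix (8000 x 46) of a context collection.

    Entry (i, j) is the fraction of contexts whose triad at position j+1 has
    row index i+1.  The denominator is always the number of contexts, so
    columns touching 'X' padding sum to less than one.
    """
    if len(contexts) == 0:
        raise ValueError("cannot compute frequencies of an empty collection")
    mat = np.zeros((N_TRIADS, N_FEATURES))
    for ctx in contexts:
        if len(ctx) != CONTEXT_LEN:
            raise ValueError(f"context must have {CONTEXT_LEN} residues")
        for j in range(N_FEATURES):
            idx = triad_row_index(ctx[j:j + 3])
            if idx != NO_INDEX:
                mat[idx - 1, j] += 1.0
    mat /= len(contexts)
    return mat


@dataclass
class PropensityModel:
    """Fitted MLPSTAAP matrices, each 8000 x 46, plus fit metadata."""

    F: np.ndarray
    FF: np.ndarray
    F_MLPSTAAP: np.ndarray
    alphabet: str = ALPHABET
    category_sizes: dict[int, int] = field(default_factory=dict)

    def fingerprint(self) -> str:
        """Stable hex digest of the propensity matrix, for artifact provenance."""
        import hashlib

        return hashlib.sha256(
            np.ascontiguousarray(self.F_MLPSTAAP).tobytes()
        ).hexdigest()[:16]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            F=self.F,
            FF=self.FF,
            F_MLPSTAAP=self.F_MLPSTAAP,
            alphabet=np.array(self.alphabet),
            category_ids=np.array(sorted(self.category_sizes), dtype=np.int64),
            category_sizes=np.array(
                [self.category_sizes[c] for c in sorted(self.category_sizes)],
                dtype=np.int64,
            ),
        )

    @classmethod
    def load(cls, path) -> "PropensityModel":
        with np.load(path) as z:
            sizes = dict(
                zip(z["category_ids"].tolist(), z["category_sizes"].tolist())
            )
            return cls(
                F=z["F"],
                FF=z["FF"],
                F_MLPSTAAP=z["F_MLPSTAAP"],
                alphabet=str(z["alphabet"]),
                category_sizes=sizes,
            )


def fit_propensity(contexts_by_category: Mapping[int, Sequence[str]]) -> PropensityModel:
    """Fit the propensity model from training contexts grouped by category.

    All 11 categories must be present with at least one context each.  For
    each category t, ``F_t`` is counted on its own contexts and ``FF_t`` on
    the pooled contexts of the other 10 categories; F, FF are unweighted
    means over the 11 categories and the propensity matrix is their
    difference.
    """
    cats = sorted(contexts_by_category)
    missing = [c for c in range(1, N_CATEGORIES + 1)
               if c not in contexts_by_category or len(contexts_by_category[c]) == 0]
    if missing:
        raise ValueError(f"missing or empty categories: {missing}")

    # Per-class raw count matrices; the pooled-complement frequencies FF_t
    # follow as (total - own counts) / (total - own size) without re-counting.
    sizes = {t: len(contexts_by_category[t]) for t in cats}
    counts = {
        t: class_frequency_matrix(contexts_by_category[t]) * sizes[t] for t in cats
    }
    total_counts = np.sum([counts[t] for t in cats], axis=0)
    n_total = sum(sizes.values())

    F = np.mean([counts[t] / sizes[t] for t in cats], axis=0)
    FF = np.mean(
        [(total_counts - counts[t]) / (n_total - sizes[t]) for t in cats], axis=0
    )

    return PropensityModel(
        F=F,
        FF=FF,
        F_MLPSTAAP=F - FF,
        category_sizes={t: len(contexts_by_category[t]) for t in cats},
    )


def encode_context(context: str, model: PropensityModel) -> np.ndarray:
    """46-dimensional feature vector of a 48-residue context."""
    if len(context) != CONTEXT_LEN:
        raise ValueError(f"context must have {CONTEXT_LEN} residues")
    out = np.zeros(N_FEATURES)
    for j in range(N_FEATURES):
        idx = triad_row_index(context[j:j + 3])
        if idx != NO_INDEX:
            out[j] = model.F_MLPSTAAP[idx - 1, j]
    return out


def encode(residues: str, model: PropensityModel) -> np.ndarray:
    """Encode a 49-mer window (or its PeptideWindow ``residues``)."""
    return encode_context(context_of(residues), model)


def encode_windows(windows: Iterable, model: PropensityModel) -> np.ndarray:
    """Stack encodings of a window collection into an (n, 46) matrix."""
    rows = []
    for w in windows:
        residues = w if isinstance(w, str) else w.residues
        rows.append(encode(residues, model))
    return np.array(rows).reshape(-1, N_FEATURES)


def group_contexts_by_category(windows: Iterable) -> dict[int, list[str]]:
    """Contexts of a PeptideWindow collection, grouped by category id."""
    grouped: dict[int, list[str]] = {}
    for w in windows:
        grouped.setdefault(w.category, []).append(context_of(w.residues))
    return grouped
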