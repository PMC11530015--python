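"""Seeded synthetic benchmark data with planted positional triad signals.

Real lysine-PTM windows differ between modification categories in which
short residue words occur near the modified site.  The generator emulates
exactly that statistical structure — and nothing else: each category draws
48 context residues i.i.d. from a background distribution and, with a
per-motif enrichment probability, overwrites a fixed 3-residue word at a
fixed context position.  The central K is then inserted to produce a
49-mer, so synthetic data flows through the production windowing entry
points unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import CONTEXT_LEN, N_FEATURES
from .windowing import (
    AMINO_ACIDS,
    CATEGORY_MODS,
    CENTER,
    N_CATEGORIES,
    PeptideWindow,
)

#: Printed training-set category ratio the default spec scales down.
REFERENCE_CATEGORY_COUNTS = (9279, 710, 600, 454, 561, 252, 360, 88, 153, 454, 73)


@dataclass(frozen=True)
class Motif:
    """A triad planted at context position ``position`` (1-based, 1..46)
    with enrichment probability ``probability``."""

    position: int
    triad: str
    probability: float

    def __post_init__(self) -> None:
        if not 1 <= self.position <= N_FEATURES:
            raise ValueError(f"motif position must be in 1..{N_FEATURES}")
        if len(self.triad) != 3 or any(a not in AMINO_ACIDS for a in self.triad):
            raise ValueError(f"motif triad must be 3 standard residues: {self.triad!r}")
        if not 0 <= self.probability <= 1:
            raise ValueError("motif probability must be in [0, 1]")


@dataclass
class SyntheticSpec:
    category_counts: tuple[int, ...]
    signal_motifs: dict[int, tuple[Motif, ...]] = field(default_factory=dict)
    background: np.ndarray | None = None  # distribution over the 20 residues
    seed: int = 0

    def __post_init__(self) -> None:
        self.category_counts = tuple(int(c) for c in self.category_counts)
        if len(self.category_counts) != N_CATEGORIES:
            raise ValueError(f"need {N_CATEGORIES} category counts")
        if any(c < 0 for c in self.category_counts):
            raise ValueError("category counts must be non-negative")
        if self.background is None:
            self.background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        self.background = np.asarray(self.background, dtype=float)
        if len(self.background) != len(AMINO_ACIDS) or not np.isclose(
            self.background.sum(), 1.0
        ):
            raise ValueError("background must be a distribution over the 20 residues")
        for cat, motifs in self.signal_motifs.items():
            if cat not in CATEGORY_MODS:
                raise ValueError(f"invalid category {cat}")
            spans = sorted((m.position, m.position + 2) for m in motifs)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping motifs in category {cat}: ambiguous plant"
                    )


def generate(spec: SyntheticSpec) -> list[PeptideWindow]:
    """Generate windows per the spec; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(AMINO_ACIDS))
    windows: list[PeptideWindow] = []
    for cat in range(1, N_CATEGORIES + 1):
        n = spec.category_counts[cat - 1]
        motifs = spec.signal_motifs.get(cat, ())
        for i in range(n):
            ctx = rng.choice(letters, size=CONTEXT_LEN, p=spec.background)
            for m in motifs:
                if rng.random() < m.probability:
                    ctx[m.position - 1:m.position + 2] = list(m.triad)
            residues = "".join(ctx[:CENTER]) + "K" + "".join(ctx[CENTER:])
            windows.append(
                PeptideWindow(f"synth_c{cat}_{i}", CENTER + 1, residues, cat)
            )
    return windows


#: One strong sequence determinant per modification type (position, triad).
#: Positions are spaced 11 apart so the four detectors stay resolvable
#: through the classifier's four stride-2 pooling stages.
TYPE_MOTIFS: dict[str, Motif] = {
    "acetyl": Motif(position=6, triad="WWW", probability=1.0),
    "crotonyl": Motif(position=17, triad="YYY", probability=1.0),
    "methyl": Motif(position=28, triad="HHH", probability=1.0),
    "succinyl": Motif(position=39, triad="FFF", probability=1.0),
}

#: Rate at which a window carries the determinant of a modification type it
#: does NOT bear (sequence mimicry).  Real proteomes contain contexts that
#: resemble a modification's determinant without the modification; this is
#: what couples the majority category to the minority signatures and makes
#: class imbalance actually matter.
DEFAULT_DECOY_PROBABILITY = 0.03


def default_imbalanced_spec(
    seed: int = 0,
    scale: float = 0.1,
    decoy_probability: float = DEFAULT_DECOY_PROBABILITY,
) -> SyntheticSpec:
    """The default study conditions: the printed training-set imbalance
    scaled by ``scale`` (floor 8 per category so 5-fold stratification stays
    possible), uniform background, and per-modification-type motifs.

    Each modification type has one strong, fully penetrant sequence
    determinant; a category (a subset of the four types) plants the
    determinants of its constituent types, the way a multiply-modified site
    carries each modification's sequence context.  Each window additionally
    carries the determinant of each type it lacks with a small decoy
    probability, so the abundant acetyl-only class overlaps the minority
    signatures and the undersampling question is non-trivial.
    """
    counts = tuple(
        max(8, int(np.floor(c * scale + 0.5))) for c in REFERENCE_CATEGORY_COUNTS
    )
    motifs = {}
    for cat, mods in CATEGORY_MODS.items():
        ms = [
            m if t in mods else Motif(m.position, m.triad, decoy_probability)
            for t, m in TYPE_MOTIFS.items()
        ]
        motifs[cat] = tuple(sorted(ms, key=lambda m: m.position))
    return SyntheticSpec(category_counts=counts, signal_motifs=motifs, seed=seed)


def write_dataset(windows: Sequence[PeptideWindow], fasta_path, annotations_path) -> None:
    """Write windows as FASTA (each 49-mer its own protein) + annotation TSV."""
    with open(fasta_path, "w") as fh:
        for w in windows:
            fh.write(f">{w.protein_id}\n{w.residues}\n")
    rows = [
        {
            "protein_id": w.protein_id,
            "position": w.center_pos,
            "mods": ",".join(sorted(w.mods)),
        }
        for w in windows
    ]
    pd.DataFrame(rows, columns=["protein_id", "position", "mods"]).to_csv(
        annotations_path, sep="\t", index=False
    )
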