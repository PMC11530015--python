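"""Peptide window extraction, category assignment and dataset assembly.

Lysine PTM sites are represented as 49-residue fragments centered on the
modified lysine (24 flanking residues on each side).  Each site carries a
non-empty subset of the four modification types — acetylation (A),
crotonylation (C), methylation (M) and succinylation (S) — and is assigned
to one of the 11 admissible modification-combination categories.  Positions
hanging over a protein terminus are padded with ``'X'``, a neutral
placeholder that contributes nothing downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("premls")

FLANK = 49 // 2  # residues on each side of the central lysine
WINDOW_LEN = 2 * FLANK + 1
CENTER = FLANK  # 0-based index of the central K

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"

#: Modification-type tokens in one-hot order (acetyl, crotonyl, methyl, succinyl).
MOD_TYPES = ("acetyl", "crotonyl", "methyl", "succinyl")
MOD_LETTERS = "ACMS"

#: Category id -> frozenset of modification types.  Only these 11 of the 15
#: non-empty subsets are admissible; sites with any of the other 4
#: combinations are excluded from datasets.
CATEGORY_MODS: dict[int, frozenset[str]] = {
    1: frozenset({"acetyl"}),
    2: frozenset({"crotonyl"}),
    3: frozenset({"methyl"}),
    4: frozenset({"succinyl"}),
    5: frozenset({"acetyl", "crotonyl"}),
    6: frozenset({"acetyl", "methyl"}),
    7: frozenset({"acetyl", "succinyl"}),
    8: frozenset({"crotonyl", "methyl"}),
    9: frozenset({"acetyl", "crotonyl", "methyl"}),
    10: frozenset({"acetyl", "crotonyl", "succinyl"}),
    11: frozenset({"acetyl", "crotonyl", "methyl", "succinyl"}),
}
_MODS_TO_CATEGORY = {mods: cat for cat, mods in CATEGORY_MODS.items()}

#: Short display label per category (matches the A/C/M/S letter order).
CATEGORY_LABELS: dict[int, str] = {
    cat: "".join(l for m, l in zip(MOD_TYPES, MOD_LETTERS) if m in mods)
    for cat, mods in CATEGORY_MODS.items()
}

N_CATEGORIES = 11


class UnsupportedCombinationError(ValueError):
    """The modification set is not one of the 11 admissible combinations."""


class NotLysineError(ValueError):
    """The annotated position does not hold a lysine."""


@dataclass(frozen=True)
class PeptideWindow:
    """A 49-residue lysine-centered fragment with provenance.

    ``center_pos`` is the 1-based residue index of the central K in the
    source protein.
    """

    protein_id: str
    center_pos: int
    residues: str
    category: int

    def __post_init__(self) -> None:
        if len(self.residues) != WINDOW_LEN:
            raise ValueError(
                f"window must have {WINDOW_LEN} residues, got {len(self.residues)}"
            )
        if self.residues[CENTER] != "K":
            raise ValueError("window center must be 'K'")
        core = self.residues.strip(PAD)
        if PAD in core:
            raise ValueError("'X' is allowed only as terminal padding")
        if self.category not in CATEGORY_MODS:
            raise ValueError(f"invalid category {self.category}")

    @property
    def label(self) -> tuple[int, int, int, int]:
        return onehot_label(self.category)

    @property
    def mods(self) -> frozenset[str]:
        return CATEGORY_MODS[self.category]


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    position: int  # 1-based
    mods: frozenset[str]


def normalize_sequence(sequence: str, protein_id: str = "?") -> str:
    """Upper-case a protein sequence and map non-standard residues to 'X'.

    B, J, O, U, Z and any other letter outside the 20-residue alphabet are
    replaced by the padding/unknown symbol with a logged warning.
    """
    seq = sequence.upper()
    bad = sorted({ch for ch in seq if ch not in AMINO_ACIDS and ch != PAD})
    if bad:
        logger.warning(
            "protein %s: non-standard residues %s normalized to 'X'",
            protein_id, "".join(bad),
        )
        seq = "".join(ch if ch in AMINO_ACIDS or ch == PAD else PAD for ch in seq)
    return seq


def extract_window(sequence: str, position: int) -> str:
    """Return the 49-residue window centered on the lysine at ``position``.

    ``position`` is 1-based.  Residues beyond either terminus are padded
    with 'X'.  Raises :class:`NotLysineError` if the centered residue is
    not K.
    """
    if not 1 <= position <= len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "K":
        raise NotLysineError(
            f"residue at position {position} is '{sequence[position - 1]}', not 'K'"
        )
    start = position - 1 - FLANK
    stop = position + FLANK
    left_pad = max(0, -start)
    right_pad = max(0, stop - len(sequence))
    core = sequence[max(0, start): min(len(sequence), stop)]
    return PAD * left_pad + core + PAD * right_pad


def assign_category(mods: Iterable[str]) -> int:
    """Map a modification set to its category id (1..11).

    Raises :class:`UnsupportedCombinationError` for the 4 combinations that
    are not admissible (e.g. methyl+succinyl alone).
    """
    modset = frozenset(mods)
    unknown = modset - set(MOD_TYPES)
    if unknown:
        raise ValueError(f"unknown modification type(s): {sorted(unknown)}")
    if not modset:
        raise ValueError("modification set must be non-empty")
    try:
        return _MODS_TO_CATEGORY[modset]
    except KeyError:
        raise UnsupportedCombinationError(
            f"unsupported combination {{{', '.join(sorted(modset))}}}"
        ) from None


def onehot_label(category: int) -> tuple[int, int, int, int]:
    """One-hot flag vector (A, C, M, S) of a category id."""
    mods = CATEGORY_MODS[category]
    return tuple(int(m in mods) for m in MOD_TYPES)  # type: ignore[return-value]


def label_to_category(flags: Sequence[int]) -> int:
    """Inverse of :func:`onehot_label`; rejects inadmissible patterns."""
    mods = frozenset(m for m, f in zip(MOD_TYPES, flags) if f)
    return assign_category(mods)


def deduplicate(windows: Iterable[PeptideWindow]) -> list[PeptideWindow]:
    """Collapse windows with identical residue strings.

    Duplicates with different categories are merged by unioning their
    modification sets and reassigning the category; if the union is not an
    admissible combination the window is dropped.  Both events are logged.
    """
    by_seq: dict[str, PeptideWindow] = {}
    merged = dropped = 0
    for w in windows:
        prev = by_seq.get(w.residues)
        if prev is None:
            by_seq[w.residues] = w
        elif prev.category != w.category:
            union = prev.mods | w.mods
            try:
                cat = assign_category(union)
            except UnsupportedCombinationError:
                dropped += 1
                del by_seq[w.residues]
                continue
            merged += 1
            by_seq[w.residues] = PeptideWindow(
                prev.protein_id, prev.center_pos, prev.residues, cat
            )
    if merged:
        logger.info("deduplicate: merged %d conflicting duplicate(s)", merged)
    if dropped:
        logger.info(
            "deduplicate: dropped %d duplicate(s) whose union combination is unsupported",
            dropped,
        )
    return list(by_seq.values())


def apply_category_floor(
    windows: Sequence[PeptideWindow], floor: int = 60
) -> list[PeptideWindow]:
    """Drop categories represented by fewer than ``floor`` windows."""
    counts: dict[int, int] = {}
    for w in windows:
        counts[w.category] = counts.get(w.category, 0) + 1
    keep = {c for c, n in counts.items() if n >= floor}
    removed = sorted(set(counts) - keep)
    if removed:
        logger.info(
            "category floor %d removed categories %s", floor, removed
        )
    return [w for w in windows if w.category in keep]


def split_dataset(
    windows: Sequence[PeptideWindow], train_fraction: float, seed: int
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Per-category stratified random split.

    Per category, ``round(train_fraction * size)`` windows (half-up) go to
    the training set.  Categories with fewer than 2 members are placed
    entirely in the training set with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[PeptideWindow] = []
    test: list[PeptideWindow] = []
    by_cat: dict[int, list[PeptideWindow]] = {}
    for w in windows:
        by_cat.setdefault(w.category, []).append(w)
    for cat in sorted(by_cat):
        members = by_cat[cat]
        if len(members) < 2:
            warnings.warn(
                f"category {cat} has {len(members)} member(s); all assigned to train",
                stacklevel=2,
            )
            train.extend(members)
            continue
        n_train = int(np.floor(train_fraction * len(members) + 0.5))
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# I/O: FASTA proteins, annotation TSV, window TSV
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by record id; residues normalized."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = normalize_sequence(str(rec.seq), rec.id)
    return seqs


def read_annotations(path) -> list[AnnotationRecord]:
    """Read the site-annotation TSV.

    Required columns: ``protein_id``, ``position`` (1-based), ``mods``
    (comma-separated tokens among acetyl|crotonyl|methyl|succinyl).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "position", "mods"):
        if col not in df.columns:
            raise ValueError(f"annotation file {path} is missing column '{col}'")
    records = []
    for row in df.itertuples(index=False):
        mods = frozenset(t.strip() for t in str(row.mods).split(",") if t.strip())
        records.append(AnnotationRecord(str(row.protein_id), int(row.position), mods))
    return records


def build_windows(
    sequences: dict[str, str], annotations: Iterable[AnnotationRecord]
) -> list[PeptideWindow]:
    """Extract one window per annotation; skip and log invalid records.

    Records pointing at a missing protein, a non-K residue, or carrying an
    unsupported modification combination are counted and skipped.
    """
    windows: list[PeptideWindow] = []
    skipped = {"missing_protein": 0, "not_lysine": 0, "unsupported_combination": 0}
    for rec in annotations:
        seq = sequences.get(rec.protein_id)
        if seq is None:
            skipped["missing_protein"] += 1
            continue
        try:
            cat = assign_category(rec.mods)
            residues = extract_window(seq, rec.position)
        except UnsupportedCombinationError:
            skipped["unsupported_combination"] += 1
            continue
        except (NotLysineError, IndexError):
            skipped["not_lysine"] += 1
            continue
        windows.append(PeptideWindow(rec.protein_id, rec.position, residues, cat))
    for reason, n in skipped.items():
        if n:
            logger.info("build_windows: skipped %d record(s): %s", n, reason)
    return windows


def windows_to_frame(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": w.protein_id,
            "center_pos": w.center_pos,
            "residues": w.residues,
            "category": w.category,
            "label": "".join(map(str, w.label)),
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows, columns=["protein_id", "center_pos", "residues", "category", "label"]
    )


def write_windows_tsv(windows: Sequence[PeptideWindow], path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path) -> list[PeptideWindow]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    return [
        PeptideWindow(str(r.protein_id), int(r.center_pos), str(r.residues), int(r.category))
        for r in df.itertuples(index=False)
    ]
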