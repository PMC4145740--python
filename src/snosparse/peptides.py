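"""Cysteine-centred peptide windows and dataset splitting.

S-nitrosylation covalently attaches a nitric-oxide moiety to a cysteine
thiol.  Site predictors operate on fixed-length fragments of the protein
around each candidate cysteine: here a 21-residue window with the cysteine
at the centre (ten flanking residues on either side).  Where the protein
ends before the window does, the missing positions are filled with the
placeholder residue ``X`` so that downstream positional encoders always see
exactly 21 positions.

The module also provides the class-stratified train/test split used to
benchmark predictors on imbalanced site data (positives are typically
outnumbered roughly 1:2 by non-modified cysteines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

WINDOW_SIZE = 21
FLANK = 10  # residues on each side of the central cysteine
CENTER = FLANK  # 0-based index of the cysteine within a window
PAD = "X"
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique identifier.

    The sequence uses the 20 standard one-letter codes; anything else
    (selenocysteine ``U``, ambiguity codes, gaps) is mapped to ``X``
    because the numeric encoders only define values for standard residues.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class PeptideWindow:
    """A 21-residue peptide around a candidate cysteine.

    ``site_pos`` is the 1-based position of the cysteine in the parent
    protein; ``label`` is 1 for an experimentally verified modification
    site and 0 for an unmodified cysteine.
    """

    protein_id: str
    site_pos: int
    residues: str
    label: int


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the stratified train/test split."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def sanitize_sequence(seq: str) -> str:
    """Uppercase a sequence and map non-standard letters to ``X``."""
    seq = seq.upper()
    return "".join(c if c in _STANDARD_SET else PAD for c in seq)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and sanitized; duplicate identifiers or an
    empty file raise ``ValueError``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of annotated cysteines.

    Expected columns: ``protein_id``, ``position`` (1-based), ``label``
    (1 = modified, 0 = unmodified).
    """
    table = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "position", "label"} - set(table.columns)
    if missing:
        raise ValueError(f"site table {path} lacks columns {sorted(missing)}")
    table["position"] = table["position"].astype(int)
    table["label"] = table["label"].astype(int)
    if not table["label"].isin([0, 1]).all():
        raise ValueError("site labels must be 0 or 1")
    return table


def _centered_window(sequence: str, site_pos: int) -> str:
    chars = []
    for offset in range(-FLANK, FLANK + 1):
        idx = site_pos - 1 + offset
        chars.append(sequence[idx] if 0 <= idx < len(sequence) else PAD)
    return "".join(chars)


def _end_padded_window(sequence: str, site_pos: int) -> str:
    # Compatibility mode: take whatever residues fall inside the sequence
    # and append 'X' at the end, so truncated windows keep their residues
    # left-aligned.  The cysteine is then not guaranteed to sit at the
    # centre; positional encoders assume centred windows.
    start = max(0, site_pos - 1 - FLANK)
    stop = min(len(sequence), site_pos + FLANK)
    fragment = sequence[start:stop]
    return fragment + PAD * (WINDOW_SIZE - len(fragment))


def extract_windows(
    proteins: Iterable[ProteinRecord],
    sites: pd.DataFrame,
    pad_mode: str = "center",
) -> list[PeptideWindow]:
    """Cut one 21-residue window per annotated cysteine.

    Parameters
    ----------
    proteins:
        Parent sequences; every ``protein_id`` in ``sites`` must appear.
    sites:
        Table with columns ``protein_id``, ``position``, ``label``; each
        position must address a ``C`` residue.
    pad_mode:
        ``"center"`` (default) pads whichever side of the window falls
        outside the sequence so the cysteine stays at position 11;
        ``"end"`` appends all padding after the available residues.
    """
    if pad_mode not in ("center", "end"):
        raise ValueError(f"unknown pad_mode {pad_mode!r}")
    by_id = {}
    for prot in proteins:
        if prot.id in by_id:
            raise ValueError(f"duplicate protein id {prot.id!r}")
        by_id[prot.id] = prot
    windows: list[PeptideWindow] = []
    for row in sites.itertuples(index=False):
        pid, pos, label = str(row.protein_id), int(row.position), int(row.label)
        if pid not in by_id:
            raise ValueError(f"site references unknown protein id {pid!r}")
        seq = by_id[pid].sequence
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"site position {pos} outside protein {pid!r} (length {len(seq)})"
            )
        if seq[pos - 1] != "C":
            raise ValueError(
                f"residue at {pid!r} position {pos} is {seq[pos - 1]!r}, not 'C'"
            )
        if pad_mode == "center":
            residues = _centered_window(seq, pos)
        else:
            residues = _end_padded_window(seq, pos)
        windows.append(PeptideWindow(pid, pos, residues, label))
    return windows


def stratified_split(
    windows: Sequence[PeptideWindow],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Split windows into train/test keeping the class ratio fixed.

    Per class, ``round(n_class * train_fraction)`` samples (round half up)
    go to the training partition; membership within a class is a
    seed-determined permutation, so the split is reproducible.
    """
    spec = SplitSpec(train_fraction=train_fraction, seed=seed)
    labels = np.array([w.label for w in windows])
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
        n_train = math.floor(idx.size * spec.train_fraction + 0.5)
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    train_idx.sort()
    test_idx.sort()
    return [windows[i] for i in train_idx], [windows[i] for i in test_idx]


def write_windows(windows: Iterable[PeptideWindow], path: str | Path) -> None:
    """Persist windows as a TSV with provenance columns."""
    frame = pd.DataFrame(
        [(w.protein_id, w.site_pos, w.residues, w.label) for w in windows],
        columns=["protein_id", "position", "window", "label"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_windows(path: str | Path) -> list[PeptideWindow]:
    frame = pd.read_csv(path, sep="\t", dtype={"window": str})
    required = {"protein_id", "position", "window", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"window table {path} lacks columns {sorted(missing)}")
    windows = []
    for row in frame.itertuples(index=False):
        if len(row.window) != WINDOW_SIZE:
            raise ValueError(
                f"window for {row.protein_id} position {row.position} has "
                f"length {len(row.window)}, expected {WINDOW_SIZE}"
            )
        windows.append(
            PeptideWindow(str(row.protein_id), int(row.position), row.window, int(row.label))
        )
    return windows
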