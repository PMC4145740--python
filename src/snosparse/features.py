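"""Numeric encoding of peptide windows.

Each 21-residue cysteine-centred window is mapped to a 666-dimensional
vector built from six blocks:

====================  =====  ==========================================
block                 width  content
====================  =====  ==========================================
conservation          420    21 positions x 20 substitution-propensity
                             channels from a PSI-BLAST PSSM
aa_factor             100    20 flank positions x 5 physicochemical
                             factors (polarity, secondary-structure
                             propensity, molecular volume, codon
                             diversity, electrostatic charge)
structure             105    21 positions x one-hot secondary structure
                             {helix, strand, other} + one-hot solvent
                             accessibility {buried, exposed}
frequency              20    amino-acid composition of the 20 flank
                             positions (the central cysteine excluded)
disorder               21    per-position intrinsic-disorder score
====================  =====  ==========================================

Window positions that fall outside the parent protein (``X`` padding)
contribute zeros in every block, a neutral value for all encoders.
Conservation, structure and disorder need per-residue predictions that
are computed by external programs; this module only reads their output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .peptides import CENTER, FLANK, PAD, STANDARD_AA, WINDOW_SIZE, PeptideWindow

# Channel order of PSI-BLAST ASCII PSSM columns.
PSSM_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
SS_CLASSES = ("helix", "strand", "other")
ACC_CLASSES = ("buried", "exposed")
FACTOR_NAMES = (
    "polarity",
    "secondary_structure",
    "molecular_volume",
    "codon_diversity",
    "charge",
)

BLOCK_WIDTHS = {
    "conservation": WINDOW_SIZE * 20,  # 420
    "aa_factor": (WINDOW_SIZE - 1) * 5,  # 100
    "structure": WINDOW_SIZE * 5,  # 105
    "frequency": 20,
    "disorder": WINDOW_SIZE,  # 21
}
BLOCK_ORDER = ("conservation", "aa_factor", "structure", "frequency", "disorder")
TOTAL_WIDTH = sum(BLOCK_WIDTHS.values())  # 666

# Synonyms accepted in per-residue annotation tables.
_SS_ALIASES = {
    "helix": "helix", "h": "helix",
    "strand": "strand", "e": "strand",
    "other": "other", "c": "other", "coil": "other", "o": "other",
}
_ACC_ALIASES = {
    "buried": "buried", "b": "buried",
    "exposed": "exposed", "e": "exposed",
}


@dataclass
class PerResidueAnnotation:
    """Externally predicted per-residue properties of one protein.

    All channels are optional; an encoder raises if the channel it needs
    is missing.  Vector lengths must equal the protein length.
    """

    protein_id: str
    pssm: np.ndarray | None = None  # (L, 20), PSSM_AA_ORDER channels
    ss: np.ndarray | None = None  # (L,) strings in SS_CLASSES
    acc: np.ndarray | None = None  # (L,) strings in ACC_CLASSES
    disorder: np.ndarray | None = None  # (L,) floats in [0, 1]

    def length(self) -> int:
        for channel in (self.pssm, self.ss, self.acc, self.disorder):
            if channel is not None:
                return len(channel)
        raise ValueError(f"annotation for {self.protein_id!r} is empty")


@dataclass
class FeatureMatrix:
    """Samples x named-features table with an aligned label vector."""

    values: pd.DataFrame
    labels: np.ndarray
    meta: pd.DataFrame | None = None  # optional protein_id/position provenance

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.values) != len(self.labels):
            raise ValueError("feature rows and labels are misaligned")
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "label", self.labels)
        if self.meta is not None:
            for i, col in enumerate(self.meta.columns):
                out.insert(1 + i, col, self.meta[col].to_numpy())
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t")
        if "label" not in frame.columns:
            raise ValueError(f"feature table {path} lacks a 'label' column")
        labels = frame.pop("label").to_numpy(dtype=int)
        meta_cols = [c for c in ("protein_id", "position") if c in frame.columns]
        meta = frame[meta_cols].reset_index(drop=True) if meta_cols else None
        values = frame.drop(columns=meta_cols).astype(float)
        return cls(values=values, labels=labels, meta=meta)


def load_factor_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the 20x5 amino-acid factor table (one 5-vector per residue).

    The packaged default is a five-factor summary of a large panel of
    physicochemical indices; a custom table with the same layout can be
    supplied instead.
    """
    if path is None:
        source = resources.files("snosparse").joinpath("data/aa_factors.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    if "aa" not in table.columns or len(table.columns) != 6:
        raise ValueError("factor table must have columns: aa + 5 factor values")
    table = table.set_index("aa")
    if sorted(table.index) != sorted(STANDARD_AA):
        raise ValueError("factor table must cover exactly the 20 standard residues")
    if table.isna().any().any():
        raise ValueError("factor table contains missing values")
    return table.astype(float)


def _window_protein_indices(window: PeptideWindow) -> list[int | None]:
    """0-based protein index for each window position, None if padded out."""
    indices: list[int | None] = []
    for i in range(WINDOW_SIZE):
        idx = window.site_pos - 1 - FLANK + i
        indices.append(idx if idx >= 0 else None)
    return indices


def _require(ann: PerResidueAnnotation | None, channel: str, window: PeptideWindow):
    if ann is None:
        raise ValueError(f"no annotation available for protein {window.protein_id!r}")
    data = getattr(ann, channel if channel != "ss_acc" else "ss")
    if channel == "ss_acc":
        if ann.ss is None or ann.acc is None:
            raise ValueError(
                f"annotation for {window.protein_id!r} lacks secondary-structure/"
                "accessibility predictions"
            )
        return ann.ss, ann.acc
    if data is None:
        raise ValueError(f"annotation for {window.protein_id!r} lacks {channel} data")
    return data


def encode_conservation(window: PeptideWindow, ann: PerResidueAnnotation) -> np.ndarray:
    """21 x 20 PSSM rows, concatenated position by position."""
    pssm = _require(ann, "pssm", window)
    out = np.zeros((WINDOW_SIZE, 20))
    for i, idx in enumerate(_window_protein_indices(window)):
        if idx is not None and idx < len(pssm):
            out[i] = pssm[idx]
    return out.ravel()


def encode_aa_factor(
    window: PeptideWindow, factor_table: pd.DataFrame | None = None
) -> np.ndarray:
    """5 physicochemical factors per flank residue (central cysteine skipped)."""
    table = load_factor_table() if factor_table is None else factor_table
    out = np.zeros((WINDOW_SIZE - 1, 5))
    flank = [r for i, r in enumerate(window.residues) if i != CENTER]
    for i, residue in enumerate(flank):
        if residue != PAD:
            out[i] = table.loc[residue].to_numpy()
    return out.ravel()


def encode_structure(window: PeptideWindow, ann: PerResidueAnnotation) -> np.ndarray:
    """Per-position one-hot secondary structure (3) + accessibility (2)."""
    ss, acc = _require(ann, "ss_acc", window)
    out = np.zeros((WINDOW_SIZE, 5))
    for i, idx in enumerate(_window_protein_indices(window)):
        if idx is None or idx >= len(ss):
            continue
        ss_label, acc_label = str(ss[idx]), str(acc[idx])
        if ss_label not in SS_CLASSES:
            raise ValueError(
                f"unknown secondary-structure class {ss_label!r} for "
                f"{window.protein_id!r}"
            )
        if acc_label not in ACC_CLASSES:
            raise ValueError(
                f"unknown accessibility class {acc_label!r} for {window.protein_id!r}"
            )
        out[i, SS_CLASSES.index(ss_label)] = 1.0
        out[i, 3 + ACC_CLASSES.index(acc_label)] = 1.0
    return out.ravel()


def encode_frequency(window: PeptideWindow) -> np.ndarray:
    """Flank amino-acid composition; 'X' contributes to no channel."""
    counts = np.zeros(20)
    for i, residue in enumerate(window.residues):
        if i == CENTER or residue == PAD:
            continue
        counts[STANDARD_AA.index(residue)] += 1
    return counts / (WINDOW_SIZE - 1)


def encode_disorder(window: PeptideWindow, ann: PerResidueAnnotation) -> np.ndarray:
    """Per-position intrinsic-disorder score."""
    disorder = _require(ann, "disorder", window)
    out = np.zeros(WINDOW_SIZE)
    for i, idx in enumerate(_window_protein_indices(window)):
        if idx is not None and idx < len(disorder):
            out[i] = disorder[idx]
    return out


def block_feature_names(block: str) -> list[str]:
    """Ordered feature names of one block (``<block>.<pos>.<channel>``)."""
    if block == "conservation":
        return [
            f"conservation.p{p + 1:02d}.{aa}"
            for p in range(WINDOW_SIZE)
            for aa in PSSM_AA_ORDER
        ]
    if block == "aa_factor":
        positions = [p for p in range(WINDOW_SIZE) if p != CENTER]
        return [
            f"aa_factor.p{p + 1:02d}.{name}" for p in positions for name in FACTOR_NAMES
        ]
    if block == "structure":
        channels = SS_CLASSES + ACC_CLASSES
        return [
            f"structure.p{p + 1:02d}.{ch}" for p in range(WINDOW_SIZE) for ch in channels
        ]
    if block == "frequency":
        return [f"frequency.{aa}" for aa in STANDARD_AA]
    if block == "disorder":
        return [f"disorder.p{p + 1:02d}" for p in range(WINDOW_SIZE)]
    raise ValueError(f"unknown feature block {block!r}")


def assemble(
    windows: Sequence[PeptideWindow],
    annotations: Mapping[str, PerResidueAnnotation] | None = None,
    blocks: Iterable[str] = BLOCK_ORDER,
    factor_table: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Encode windows into a feature matrix, block by block.

    ``blocks`` selects which of the five blocks to emit (always in the
    canonical order); disabling a block shrinks the matrix accordingly.
    Blocks that need external predictions (conservation, structure,
    disorder) require an annotation for every window's protein.
    """
    blocks = [b for b in BLOCK_ORDER if b in set(blocks)]
    if not blocks:
        raise ValueError("at least one feature block must be enabled")
    if factor_table is None and "aa_factor" in blocks:
        factor_table = load_factor_table()
    names = [name for b in blocks for name in block_feature_names(b)]
    annotations = annotations or {}

    rows = np.zeros((len(windows), len(names)))
    for r, window in enumerate(windows):
        ann = annotations.get(window.protein_id)
        parts = []
        for b in blocks:
            if b == "conservation":
                parts.append(encode_conservation(window, ann))
            elif b == "aa_factor":
                parts.append(encode_aa_factor(window, factor_table))
            elif b == "structure":
                parts.append(encode_structure(window, ann))
            elif b == "frequency":
                parts.append(encode_frequency(window))
            elif b == "disorder":
                parts.append(encode_disorder(window, ann))
        vector = np.concatenate(parts)
        if vector.size != len(names):  # pragma: no cover - internal consistency
            raise AssertionError("assembled width does not match declared blocks")
        rows[r] = vector

    values = pd.DataFrame(rows, columns=names)
    labels = np.array([w.label for w in windows], dtype=int)
    meta = pd.DataFrame(
        {
            "protein_id": [w.protein_id for w in windows],
            "position": [w.site_pos for w in windows],
        }
    )
    return FeatureMatrix(values=values, labels=labels, meta=meta)


# ---------------------------------------------------------------------------
# Readers for externally computed per-residue predictions
# ---------------------------------------------------------------------------

def read_pssm(
    path: str | Path, scale: str = "logodds", protein_id: str | None = None
) -> PerResidueAnnotation:
    """Parse a PSI-BLAST ASCII PSSM file.

    The data section has one line per residue: index, residue letter, 20
    log-odds scores and (optionally) 20 weighted-observation percentages.
    ``scale`` selects which section to keep: ``"logodds"`` or ``"percent"``.
    """
    if scale not in ("logodds", "percent"):
        raise ValueError(f"unknown PSSM scale {scale!r}")
    path = Path(path)
    rows: list[list[float]] = []
    expected_pos = 1
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens or not tokens[0].isdigit():
            continue  # header, legend or footer line
        if len(tokens) < 22:
            raise ValueError(
                f"{path} line {lineno}: expected at least 22 columns, got {len(tokens)}"
            )
        pos = int(tokens[0])
        if pos != expected_pos:
            raise ValueError(
                f"{path} line {lineno}: residue index {pos}, expected {expected_pos}"
            )
        expected_pos += 1
        if scale == "percent":
            if len(tokens) < 42:
                raise ValueError(
                    f"{path} line {lineno}: no percentage section "
                    f"({len(tokens)} columns)"
                )
            values = tokens[22:42]
        else:
            values = tokens[2:22]
        try:
            rows.append([float(v) for v in values])
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: non-numeric PSSM entry") from exc
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    return PerResidueAnnotation(
        protein_id=protein_id or path.stem, pssm=np.array(rows)
    )


def write_pssm(
    path: str | Path, sequence: str, matrix: np.ndarray, scale_int: bool = True
) -> None:
    """Write a minimal PSI-BLAST-style ASCII PSSM (log-odds section only)."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(sequence), 20):
        raise ValueError("PSSM matrix must be (sequence length, 20)")
    fmt = "{:.0f}" if scale_int else "{:.3f}"
    lines = ["", "Last position-specific scoring matrix computed", "    " + " ".join(PSSM_AA_ORDER)]
    for i, (residue, row) in enumerate(zip(sequence, matrix), start=1):
        body = " ".join(fmt.format(v) for v in row)
        lines.append(f"{i} {residue} {body} {body}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm_dir(
    directory: str | Path, scale: str = "logodds"
) -> dict[str, PerResidueAnnotation]:
    """Read every ``<protein_id>.pssm`` file in a directory."""
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.pssm")):
        out[path.stem] = read_pssm(path, scale=scale)
    if not out:
        raise ValueError(f"no .pssm files found in {directory}")
    return out


def _read_positional_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = set(columns) - set(frame.columns)
    if missing:
        raise ValueError(f"{path} lacks columns {sorted(missing)}")
    frame["position"] = frame["position"].astype(int)
    for pid, group in frame.groupby("protein_id", sort=False):
        positions = group["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(positions) + 1)):
            raise ValueError(
                f"{path}: positions for protein {pid!r} are not contiguous from 1"
            )
    return frame


def read_ss_acc(path: str | Path) -> dict[str, PerResidueAnnotation]:
    """Read per-residue secondary-structure and accessibility predictions.

    TSV columns: ``protein_id``, ``position``, ``ss`` (helix/strand/other,
    or H/E/C), ``acc`` (buried/exposed, or B/E).
    """
    frame = _read_positional_table(path, ["protein_id", "position", "ss", "acc"])
    out = {}
    for pid, group in frame.groupby("protein_id", sort=False):
        try:
            ss = np.array([_SS_ALIASES[str(v).lower()] for v in group["ss"]])
            acc = np.array([_ACC_ALIASES[str(v).lower()] for v in group["acc"]])
        except KeyError as exc:
            raise ValueError(
                f"{path}: unknown class label {exc.args[0]!r} for protein {pid!r}"
            ) from None
        out[str(pid)] = PerResidueAnnotation(protein_id=str(pid), ss=ss, acc=acc)
    return out


def read_disorder(path: str | Path) -> dict[str, PerResidueAnnotation]:
    """Read per-residue disorder scores (TSV: protein_id, position, score)."""
    frame = _read_positional_table(path, ["protein_id", "position", "score"])
    out = {}
    for pid, group in frame.groupby("protein_id", sort=False):
        scores = group["score"].to_numpy(dtype=float)
        if np.any((scores < 0) | (scores > 1)):
            raise ValueError(f"{path}: disorder scores for {pid!r} outside [0, 1]")
        out[str(pid)] = PerResidueAnnotation(protein_id=str(pid), disorder=scores)
    return out


def merge_annotations(
    *sources: Mapping[str, PerResidueAnnotation],
) -> dict[str, PerResidueAnnotation]:
    """Combine channel-specific annotation dicts into one per protein.

    Channel lengths for the same protein must agree across sources.
    """
    merged: dict[str, PerResidueAnnotation] = {}
    for source in sources:
        for pid, ann in source.items():
            if pid not in merged:
                merged[pid] = PerResidueAnnotation(protein_id=pid)
            target = merged[pid]
            for channel in ("pssm", "ss", "acc", "disorder"):
                value = getattr(ann, channel)
                if value is None:
                    continue
                if getattr(target, channel) is not None:
                    raise ValueError(f"duplicate {channel} annotation for {pid!r}")
                setattr(target, channel, value)
    for pid, ann in merged.items():
        lengths = {
            len(v)
            for v in (ann.pssm, ann.ss, ann.acc, ann.disorder)
            if v is not None
        }
        if len(lengths) > 1:
            raise ValueError(f"annotation channels for {pid!r} disagree on length")
    return merged
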