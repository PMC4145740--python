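"""Synthetic peptide and feature-matrix generators for pipeline testing.

Two generators are provided.  :func:`make_feature_data` produces a plain
two-class numeric matrix — a controllable number of informative columns
whose class means are separated by ``effect`` standard deviations, plus
pure-noise columns — for exercising the ranking, selection and classifier
stages in isolation.  :func:`make_peptide_data` emulates the shape of a
cysteine-site dataset end to end: random protein sequences with planted
annotated cysteines at a roughly 1:2 positive:negative ratio, a
compositional bias (acidic flank enrichment) in the positive class so the
sequence-derived feature blocks carry signal, and internally consistent
synthetic per-residue predictions (PSSM, secondary structure, solvent
accessibility, disorder) for the annotation-driven blocks.

Neither generator attempts to mimic true S-nitrosylation motifs; the goal
is a dataset whose signal is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import PSSM_AA_ORDER, FeatureMatrix, PerResidueAnnotation, write_pssm
from .peptides import STANDARD_AA, ProteinRecord

# 1:2 positive:negative default mirrors the class skew of curated
# cysteine-site collections.
DEFAULT_N_POS = 67
DEFAULT_N_NEG = 133


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the numeric-feature generator."""

    n_pos: int = DEFAULT_N_POS
    n_neg: int = DEFAULT_N_NEG
    n_informative: int = 5
    n_noise: int = 45
    effect: float = 3.0  # class mean separation, in SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.n_informative, self.n_noise) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_informative + self.n_noise < 1:
            raise ValueError("at least one feature is required")


def make_feature_data(spec: SyntheticSpec = SyntheticSpec()) -> FeatureMatrix:
    """Two-class Gaussian feature matrix with known informative columns.

    Informative columns are N(+effect/2, 1) in the positive class and
    N(-effect/2, 1) in the negative class; noise columns are N(0, 1)
    everywhere.  Column names ("informative.<i>" / "noise.<j>") flag the
    ground truth; column and row order are shuffled deterministically
    under the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    p = spec.n_informative + spec.n_noise
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])

    X = rng.standard_normal((n, p))
    shift = np.where(labels == 1, spec.effect / 2.0, -spec.effect / 2.0)
    X[:, : spec.n_informative] += shift[:, None]

    names = [f"informative.{i + 1}" for i in range(spec.n_informative)] + [
        f"noise.{j + 1}" for j in range(spec.n_noise)
    ]
    col_perm = rng.permutation(p)
    row_perm = rng.permutation(n)
    values = pd.DataFrame(
        X[np.ix_(row_perm, col_perm)], columns=[names[c] for c in col_perm]
    )
    return FeatureMatrix(values=values, labels=labels[row_perm])


def make_low_coherence_dictionary(
    rng: np.random.Generator,
    n_rows: int = 6,
    n_cols: int = 10,
    target: float = 0.45,
    max_iter: int = 200,
) -> np.ndarray:
    """Random unit-norm dictionary with pairwise coherence below ``target``.

    Independent Gaussian columns in low dimension almost never satisfy a
    coherence bound near the Welch limit, so the frame is constructed by
    alternating projections: clip the off-diagonal Gram entries at the
    target, project the Gram matrix back to rank ``n_rows``, and
    renormalize.  Used to build sparse-recovery test systems on which
    greedy pursuit is provably well behaved.
    """
    if n_cols <= n_rows:
        raise ValueError("need an overcomplete dictionary (n_cols > n_rows)")
    welch = np.sqrt((n_cols - n_rows) / (n_rows * (n_cols - 1)))
    if target <= welch:
        raise ValueError(f"target coherence {target} below the Welch bound {welch:.3f}")
    A = rng.normal(size=(n_rows, n_cols))
    A /= np.linalg.norm(A, axis=0)
    for _ in range(max_iter):
        gram = A.T @ A
        off = np.abs(gram - np.eye(n_cols))
        if off.max() < target:
            break
        clipped = np.clip(gram, -target, target)
        np.fill_diagonal(clipped, 1.0)
        eigenvalues, eigenvectors = np.linalg.eigh(clipped)
        top = eigenvalues[-n_rows:].clip(min=0.0)
        A = (eigenvectors[:, -n_rows:] * np.sqrt(top)).T
        A /= np.linalg.norm(A, axis=0)
    return A


# Flank residue distributions for the peptide generator.  The positive
# class enriches acidic residues (D, E), a purely synthetic signal that
# the composition and physicochemical blocks can pick up.
_BACKGROUND = {aa: 1.0 for aa in STANDARD_AA}
_BACKGROUND["C"] = 0.3  # keep incidental cysteines rare
_POSITIVE_BIAS = dict(_BACKGROUND, D=4.0, E=4.0)


def _probs(weights: dict[str, float]) -> np.ndarray:
    w = np.array([weights[aa] for aa in STANDARD_AA])
    return w / w.sum()


def make_peptide_data(
    n_pos: int = DEFAULT_N_POS,
    n_neg: int = DEFAULT_N_NEG,
    seed: int = 0,
    min_length: int = 25,
    max_length: int = 60,
) -> tuple[list[ProteinRecord], pd.DataFrame, dict[str, PerResidueAnnotation]]:
    """Generate proteins, one annotated cysteine site each, and annotations.

    Returns ``(proteins, site table, annotations)`` ready for
    :func:`snosparse.peptides.extract_windows` and
    :func:`snosparse.features.assemble`.  Positives carry an acidic flank
    bias and elevated flank disorder; the synthetic PSSM encodes residue
    identity with additive noise so the conservation block also reflects
    composition.
    """
    if min(n_pos, n_neg) < 1:
        raise ValueError("both classes need at least one sample")
    rng = np.random.default_rng(seed)
    bg = _probs(_BACKGROUND)
    biased = _probs(_POSITIVE_BIAS)

    proteins: list[ProteinRecord] = []
    rows = []
    annotations: dict[str, PerResidueAnnotation] = {}
    labels = [1] * n_pos + [0] * n_neg

    for i, label in enumerate(labels):
        pid = f"syn{i + 1:04d}"
        length = int(rng.integers(min_length, max_length + 1))
        site = int(rng.integers(1, length + 1))
        residues = rng.choice(list(STANDARD_AA), size=length, p=bg)
        if label == 1:
            lo, hi = max(0, site - 11), min(length, site + 10)
            flank_len = hi - lo
            residues[lo:hi] = rng.choice(list(STANDARD_AA), size=flank_len, p=biased)
        residues[site - 1] = "C"
        sequence = "".join(residues)
        proteins.append(ProteinRecord(pid, sequence))
        rows.append((pid, site, label))

        pssm = rng.normal(0.0, 1.0, size=(length, 20))
        for pos, residue in enumerate(sequence):
            pssm[pos, PSSM_AA_ORDER.index(residue)] += 4.0
        ss = rng.choice(["helix", "strand", "other"], size=length, p=[0.35, 0.25, 0.4])
        acc = rng.choice(["buried", "exposed"], size=length, p=[0.45, 0.55])
        disorder = rng.uniform(0.0, 0.6, size=length)
        if label == 1:
            lo, hi = max(0, site - 11), min(length, site + 10)
            disorder[lo:hi] = np.clip(disorder[lo:hi] + 0.3, 0.0, 1.0)
        annotations[pid] = PerResidueAnnotation(
            protein_id=pid, pssm=pssm, ss=ss, acc=acc, disorder=disorder
        )

    sites = pd.DataFrame(rows, columns=["protein_id", "position", "label"])
    return proteins, sites, annotations


def write_peptide_dataset(
    directory: str | Path,
    proteins: list[ProteinRecord],
    sites: pd.DataFrame,
    annotations: dict[str, PerResidueAnnotation],
) -> None:
    """Write a generated peptide dataset in the formats the CLI consumes.

    Produces ``proteins.fasta``, ``sites.tsv``, ``pssm/<id>.pssm``,
    ``ss_acc.tsv`` and ``disorder.tsv`` under ``directory``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "proteins.fasta", "w") as handle:
        for prot in proteins:
            handle.write(f">{prot.id}\n{prot.sequence}\n")
    sites.to_csv(directory / "sites.tsv", sep="\t", index=False)

    pssm_dir = directory / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    ss_rows = []
    dis_rows = []
    for prot in proteins:
        ann = annotations[prot.id]
        write_pssm(pssm_dir / f"{prot.id}.pssm", prot.sequence, ann.pssm, scale_int=False)
        for pos in range(len(prot.sequence)):
            ss_rows.append((prot.id, pos + 1, ann.ss[pos], ann.acc[pos]))
            dis_rows.append((prot.id, pos + 1, round(float(ann.disorder[pos]), 6)))
    pd.DataFrame(ss_rows, columns=["protein_id", "position", "ss", "acc"]).to_csv(
        directory / "ss_acc.tsv", sep="\t", index=False
    )
    pd.DataFrame(dis_rows, columns=["protein_id", "position", "score"]).to_csv(
        directory / "disorder.tsv", sep="\t", index=False
    )
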