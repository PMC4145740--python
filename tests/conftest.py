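"""Shared fixtures and helpers for the snosparse test suite."""

from __future__ import annotations

import numpy as np
import pytest

from snosparse.peptides import CENTER, WINDOW_SIZE, PeptideWindow


def make_window(
    residues: str,
    protein_id: str = "p1",
    site_pos: int = 11,
    label: int = 1,
) -> PeptideWindow:
    """Build a window from a literal 21-residue string."""
    assert len(residues) == WINDOW_SIZE
    return PeptideWindow(protein_id, site_pos, residues, label)


def all_x_window(label: int = 1) -> PeptideWindow:
    """A window that is entirely padding except the central cysteine."""
    residues = "X" * CENTER + "C" + "X" * CENTER
    return make_window(residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
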