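"""Sequence-coupling probability tables and the difference feature encoding.

Each flank position of a lysine-centred window is described by a
probability estimated separately from the modified (positive) and
unmodified (negative) window subsets:

* the two positions immediately adjacent to the central K get the
  *marginal* probability of their residue at that position;
* every other flank position gets the *conditional* probability of its
  residue given the residue at the neighbouring position closer to K.

A window is encoded as the vector of positive-minus-negative
probabilities over its ``2*zeta`` flank positions (28 dimensions for the
default half-window ``zeta = 14``), so every component lies in [-1, 1].

Probabilities are maximum-likelihood count ratios over the 21-letter
alphabet (padding 'X' included); 0/0 is defined as 0, with no smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .windowing import (
    ALPHABET,
    ALPHABET_INDEX,
    NEGATIVE,
    POSITIVE,
    PeptideWindow,
    WindowDataset,
)

N_ALPHA = len(ALPHABET)  # 21


class CouplingError(ValueError):
    """Raised for inconsistent windows or degenerate fitting subsets."""


def flank_positions(zeta: int) -> list[int]:
    """Flank indices 1..2*zeta (the central K carries no feature)."""
    return list(range(1, 2 * zeta + 1))


def marginal_positions(zeta: int) -> tuple[int, int]:
    """The two centre-adjacent flank indices (14 and 15 for zeta=14)."""
    return (zeta, zeta + 1)


def conditioning_neighbor(position: int, zeta: int) -> int:
    """Flank index of the neighbour closer to K that *position* conditions on."""
    if position < 1 or position > 2 * zeta:
        raise CouplingError(f"flank position {position} outside 1..{2 * zeta}")
    if position in marginal_positions(zeta):
        raise CouplingError(f"position {position} is marginal, not conditional")
    return position + 1 if position < zeta else position - 1


def _flank_matrix(windows: Sequence[PeptideWindow], zeta: int) -> np.ndarray:
    """Integer-encode flank residues: shape (n_windows, 2*zeta)."""
    width = 2 * zeta + 1
    rows = np.empty((len(windows), 2 * zeta), dtype=np.intp)
    for i, w in enumerate(windows):
        if len(w.residues) != width:
            raise CouplingError(
                f"window {w.protein_id}:{w.position} has length "
                f"{len(w.residues)}, expected {width}"
            )
        flank = w.residues[:zeta] + w.residues[zeta + 1 :]
        rows[i] = [ALPHABET_INDEX[c] for c in flank]
    return rows


def fit_tables(
    windows: Sequence[PeptideWindow], zeta: int
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Estimate per-position probability tables from one window subset.

    Returns ``(conditional, marginal)`` where ``conditional[p]`` is a
    21x21 array ``P[a, b] = P(residue a at p | residue b at neighbour)``
    and ``marginal[p]`` is a length-21 array of residue frequencies.
    An empty subset yields all-zero tables and a warning.
    """
    m_left, m_right = marginal_positions(zeta)
    conditional: dict[int, np.ndarray] = {}
    marginal: dict[int, np.ndarray] = {}
    if not windows:
        warnings.warn("fitting coupling tables on an empty subset; tables are zero")
        for p in flank_positions(zeta):
            if p in (m_left, m_right):
                marginal[p] = np.zeros(N_ALPHA)
            else:
                conditional[p] = np.zeros((N_ALPHA, N_ALPHA))
        return conditional, marginal

    F = _flank_matrix(windows, zeta)
    n = len(windows)
    for p in flank_positions(zeta):
        col = F[:, p - 1]
        if p in (m_left, m_right):
            marginal[p] = np.bincount(col, minlength=N_ALPHA) / n
        else:
            q = conditioning_neighbor(p, zeta)
            neighbor = F[:, q - 1]
            pair_counts = np.zeros((N_ALPHA, N_ALPHA))
            np.add.at(pair_counts, (col, neighbor), 1.0)
            cond_counts = pair_counts.sum(axis=0)
            with np.errstate(invalid="ignore"):
                table = pair_counts / cond_counts[None, :]
            table[:, cond_counts == 0] = 0.0  # 0/0 := 0 for unseen conditioners
            conditional[p] = table
    return conditional, marginal


@dataclass
class CouplingModel:
    """Positive- and negative-subset probability tables for one ``zeta``."""

    zeta: int
    positive_conditional: dict[int, np.ndarray]
    positive_marginal: dict[int, np.ndarray]
    negative_conditional: dict[int, np.ndarray]
    negative_marginal: dict[int, np.ndarray]
    n_pos: int
    n_neg: int

    @property
    def feature_dim(self) -> int:
        return 2 * self.zeta


def fit_model(dataset: WindowDataset) -> CouplingModel:
    """Fit positive tables on positive windows and negative tables on negatives."""
    pos = dataset.subset(POSITIVE)
    neg = dataset.subset(NEGATIVE)
    if not pos or not neg:
        raise CouplingError(
            f"coupling model needs both classes; got {len(pos)} positive and "
            f"{len(neg)} negative windows"
        )
    pc, pm = fit_tables(pos, dataset.zeta)
    nc, nm = fit_tables(neg, dataset.zeta)
    return CouplingModel(
        zeta=dataset.zeta,
        positive_conditional=pc,
        positive_marginal=pm,
        negative_conditional=nc,
        negative_marginal=nm,
        n_pos=len(pos),
        n_neg=len(neg),
    )


def _lookup(
    conditional: dict[int, np.ndarray],
    marginal: dict[int, np.ndarray],
    F: np.ndarray,
    zeta: int,
) -> np.ndarray:
    """Per-window probability at every flank position; F is the int flank matrix."""
    out = np.empty((F.shape[0], 2 * zeta))
    for p in flank_positions(zeta):
        if p in marginal:
            out[:, p - 1] = marginal[p][F[:, p - 1]]
        else:
            q = conditioning_neighbor(p, zeta)
            out[:, p - 1] = conditional[p][F[:, p - 1], F[:, q - 1]]
    return out


def encode_windows(
    windows: Sequence[PeptideWindow], model: CouplingModel
) -> np.ndarray:
    """Encode windows as the positive-minus-negative probability matrix.

    Returns an array of shape ``(n_windows, 2*zeta)`` with entries in
    [-1, 1]; column ``i`` holds the component for flank position ``i+1``.
    """
    F = _flank_matrix(windows, model.zeta)
    pos = _lookup(model.positive_conditional, model.positive_marginal, F, model.zeta)
    neg = _lookup(model.negative_conditional, model.negative_marginal, F, model.zeta)
    return pos - neg


def encode_window(window: PeptideWindow, model: CouplingModel) -> np.ndarray:
    """Encode a single window; see :func:`encode_windows`."""
    return encode_windows([window], model)[0]


def encode_dataset(
    dataset: WindowDataset, model: CouplingModel
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every window; returns ``(features, labels)`` with labels +/-1."""
    X = encode_windows(dataset.windows, model)
    y = np.array([1 if w.label == POSITIVE else -1 for w in dataset.windows])
    return X, y


# ---------------------------------------------------------------------------
# Table export / import (conditional: 441 residue-pair rows; marginal: 21 rows)

def _pair_labels() -> list[str]:
    return [f"{a}|{b}" for a in ALPHABET for b in ALPHABET]


def conditional_frame(model: CouplingModel) -> pd.DataFrame:
    """441-row frame of conditional probabilities, columns ``subset:position``."""
    data = {}
    for subset, tables in (
        ("positive", model.positive_conditional),
        ("negative", model.negative_conditional),
    ):
        for p in sorted(tables):
            data[f"{subset}:{p}"] = tables[p].ravel()
    return pd.DataFrame(data, index=_pair_labels())


def marginal_frame(model: CouplingModel) -> pd.DataFrame:
    """21-row frame of marginal probabilities, columns ``subset:position``."""
    data = {}
    for subset, tables in (
        ("positive", model.positive_marginal),
        ("negative", model.negative_marginal),
    ):
        for p in sorted(tables):
            data[f"{subset}:{p}"] = tables[p]
    return pd.DataFrame(data, index=list(ALPHABET))


def export_tables(
    model: CouplingModel, path_conditional: str | Path, path_marginal: str | Path
) -> None:
    """Write the fitted tables as two CSV files.

    A header comment records ``zeta`` and the subset sizes so the model
    round-trips through :func:`load_tables`.
    """
    meta = f"# zeta={model.zeta} n_pos={model.n_pos} n_neg={model.n_neg}\n"
    for path, frame in (
        (path_conditional, conditional_frame(model)),
        (path_marginal, marginal_frame(model)),
    ):
        with open(path, "w") as fh:
            fh.write(meta)
            frame.to_csv(fh, index_label="residue")


def load_tables(
    path_conditional: str | Path, path_marginal: str | Path
) -> CouplingModel:
    """Reconstruct a :class:`CouplingModel` from its CSV exports."""
    def read(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
        with open(path) as fh:
            first = fh.readline().lstrip("# ").strip()
            meta = dict(kv.split("=") for kv in first.split())
            frame = pd.read_csv(fh, index_col=0)
        return meta, frame

    meta, cond = read(path_conditional)
    meta2, marg = read(path_marginal)
    if meta != meta2:
        raise CouplingError("conditional and marginal exports disagree on metadata")
    zeta = int(meta["zeta"])
    tables: dict[str, dict[int, np.ndarray]] = {
        "positive_conditional": {}, "negative_conditional": {},
        "positive_marginal": {}, "negative_marginal": {},
    }
    for col in cond.columns:
        subset, p = col.split(":")
        tables[f"{subset}_conditional"][int(p)] = (
            cond[col].to_numpy().reshape(N_ALPHA, N_ALPHA)
        )
    for col in marg.columns:
        subset, p = col.split(":")
        tables[f"{subset}_marginal"][int(p)] = marg[col].to_numpy()
    return CouplingModel(
        zeta=zeta,
        positive_conditional=tables["positive_conditional"],
        positive_marginal=tables["positive_marginal"],
        negative_conditional=tables["negative_conditional"],
        negative_marginal=tables["negative_marginal"],
        n_pos=int(meta["n_pos"]),
        n_neg=int(meta["n_neg"]),
    )
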