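"""Corrected structural-connectivity matrices from streamline counts.

Probabilistic tractography yields a directed count of streamlines between
every ordered pair of regions.  The pipeline (i) symmetrizes by averaging
the two directions, and (ii) corrects for unequal inter-region distances and
gray-matter region sizes:

    w(i, j) = s(i, j) * d(i, j)**alpha / (v_i + v_j)**beta

with defaults alpha = beta = 1: multiplying by centroid distance offsets the
attenuation of probabilistic tracking with path length, dividing by the
summed region volumes offsets seed-count differences.  Per-participant
matrices are flattened into a cohort edge table (participants x 190
undirected edges for 20 regions) for the factor analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EDGE_SEP = "|"


class ConnectomeError(ValueError):
    """Raised for malformed counts, distances, volumes, or region mismatches."""


def edge_label(a: str, b: str) -> str:
    return f"{a}{EDGE_SEP}{b}"


def split_edge(label: str) -> tuple[str, str]:
    a, b = label.split(EDGE_SEP)
    return a, b


def edge_labels(regions: list[str]) -> list[str]:
    """All undirected edges, lexicographic by region *index* (i < j)."""
    return [
        edge_label(regions[i], regions[j])
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ]


@dataclass
class ConnectivityMatrix:
    """Symmetric corrected edge weights with zero diagonal for one participant."""

    weights: pd.DataFrame
    participant: str = ""

    def __post_init__(self) -> None:
        w = self.weights
        if not w.index.equals(w.columns):
            raise ConnectomeError("connectivity matrix must have identical row/column regions")
        vals = w.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, rtol=1e-10, atol=1e-12):
            raise ConnectomeError("connectivity matrix must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise ConnectomeError("connectivity matrix must have a zero diagonal")
        if np.any(vals < 0):
            raise ConnectomeError("connectivity weights must be nonnegative")

    @property
    def regions(self) -> list[str]:
        return list(self.weights.index)


def _check_square(df: pd.DataFrame, what: str) -> None:
    if not df.index.equals(df.columns):
        raise ConnectomeError(f"{what} must be square with identical row/column labels")


def symmetrize(raw: pd.DataFrame) -> pd.DataFrame:
    """Average streamline counts over both directions; diagonal set to 0."""
    _check_square(raw, "raw streamline counts")
    vals = raw.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ConnectomeError("streamline counts must be finite")
    if np.any(vals < 0):
        i, j = np.argwhere(vals < 0)[0]
        raise ConnectomeError(
            f"negative streamline count at ({raw.index[i]!r}, {raw.columns[j]!r})"
        )
    sym = (vals + vals.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    return pd.DataFrame(sym, index=raw.index, columns=raw.columns)


def correct(
    sym: pd.DataFrame,
    distances: pd.DataFrame,
    volumes: pd.Series,
    alpha: float = 1.0,
    beta: float = 1.0,
    participant: str = "",
) -> ConnectivityMatrix:
    """Distance/size correction: w = s * d**alpha / (v_i + v_j)**beta."""
    _check_square(sym, "symmetric counts")
    _check_square(distances, "distance matrix")
    if not sym.index.equals(distances.index):
        raise ConnectomeError("counts and distances must share the same region list")
    missing = [r for r in sym.index if r not in volumes.index]
    if missing:
        raise ConnectomeError(f"volumes missing for regions: {missing}")
    v = volumes.reindex(sym.index).to_numpy(dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        bad = sym.index[(~np.isfinite(v)) | (v <= 0)][0]
        raise ConnectomeError(f"region {bad!r} has non-positive volume")
    d = distances.to_numpy(dtype=float)
    off = ~np.eye(len(sym), dtype=bool)
    if np.any(d[off] <= 0):
        raise ConnectomeError("inter-region distances must be positive")
    if not np.allclose(d, d.T, rtol=1e-9):
        raise ConnectomeError("distance matrix must be symmetric")
    s = sym.to_numpy(dtype=float)
    vsum = v[:, None] + v[None, :]
    with np.errstate(divide="ignore"):
        w = s * np.where(off, d, 0.0) ** alpha / vsum**beta
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        pd.DataFrame(w, index=sym.index, columns=sym.columns), participant=participant
    )


def assemble_cohort(matrices: dict[str, ConnectivityMatrix]) -> pd.DataFrame:
    """Participants x undirected-edges table; columns in fixed edge order."""
    if not matrices:
        raise ConnectomeError("no connectivity matrices supplied")
    participants = list(matrices)
    regions = matrices[participants[0]].regions
    cols = edge_labels(regions)
    rows = {}
    for p in participants:
        m = matrices[p]
        if m.regions != regions:
            raise ConnectomeError(
                f"participant {p!r} has a different region list than {participants[0]!r}"
            )
        vals = m.weights.to_numpy(dtype=float)
        iu = np.triu_indices(len(regions), k=1)
        rows[p] = vals[iu]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "participant"
    return table


def edge_table_to_matrices(table: pd.DataFrame, regions: list[str]) -> dict[str, ConnectivityMatrix]:
    """Inverse of :func:`assemble_cohort` (bit-exact round trip)."""
    expected = edge_labels(regions)
    if list(table.columns) != expected:
        raise ConnectomeError("edge table columns do not match the expected edge ordering")
    iu = np.triu_indices(len(regions), k=1)
    out = {}
    for p, row in table.iterrows():
        w = np.zeros((len(regions), len(regions)))
        w[iu] = row.to_numpy(dtype=float)
        w = w + w.T
        out[str(p)] = ConnectivityMatrix(
            pd.DataFrame(w, index=regions, columns=regions), participant=str(p)
        )
    return out


def incident_edges(regions: list[str], region: str) -> list[str]:
    """The R-1 edge labels incident to ``region``, ordered by partner index."""
    if region not in regions:
        raise ConnectomeError(f"unknown region {region!r}")
    i = regions.index(region)
    labels = []
    for j, other in enumerate(regions):
        if j == i:
            continue
        a, b = (i, j) if i < j else (j, i)
        labels.append(edge_label(regions[a], regions[b]))
    return labels


def region_edge_view(table: pd.DataFrame, regions: list[str], region: str) -> pd.DataFrame:
    """Sub-table of the edges incident to one region."""
    return table[incident_edges(regions, region)]
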