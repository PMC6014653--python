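"""Q-mode correlation affinities between population mean vectors.

Craniometric affinity between population samples is measured on a fixed panel
of 16 of Martin's standard measurements. Each measurement column is
z-standardized across the groups in the table (mean 0, unit variance,
``n - 1`` denominator) so that large absolute measurements (e.g. cranial
length, ~180 mm) do not dominate small ones (e.g. simotic subtense, ~4 mm).
The Q-mode correlation r between two groups is then the Pearson correlation
of their standardized 16-element profiles, and ``d = 1 - r`` serves as the
dissimilarity fed to the split-network construction.

Note the Q/R distinction: correlation is computed *between groups across
measurements* (Q-mode), not between measurements across groups (R-mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import InsufficientDataError, ValidationError

log = logging.getLogger(__name__)

#: The canonical 16-measurement panel (Martin numbers).
DEFAULT_PANEL_CODES = (
    "M1", "M8", "M9", "M17", "M43(1)", "M43c", "M45", "M46b",
    "M46c", "M48", "M51", "M52", "M54", "M55", "M57", "M57a",
)


@dataclass(frozen=True)
class MeasurementPanel:
    """Ordered set of measurement identifiers."""

    codes: tuple[str, ...] = DEFAULT_PANEL_CODES

    def __post_init__(self):
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("measurement codes must be unique")
        if not self.codes:
            raise ValidationError("panel is empty")


@dataclass
class GroupMeanTable:
    """Group-by-measurement table of mean values in millimetres."""

    groups: list[str]
    panel: MeasurementPanel
    values: np.ndarray  # shape (n_groups, n_codes)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.groups), len(self.panel.codes)):
            raise ValidationError("value matrix shape does not match labels/panel")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.groups, columns=list(self.panel.codes))


@dataclass
class AffinityMatrix:
    """Symmetric Q-mode correlation matrix with unit diagonal."""

    groups: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.groups)
        if self.r.shape != (n, n):
            raise ValidationError("affinity matrix is not square")
        if not np.allclose(self.r, self.r.T, atol=1e-9):
            raise ValidationError("affinity matrix is not symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.groups, columns=self.groups)


@dataclass
class CranioDistanceMatrix:
    """Symmetric ``1 - r`` distance matrix, zero diagonal, entries in [0, 2]."""

    groups: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.groups)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix is not square")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.groups, columns=self.groups)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_phylip(self, path) -> None:
        """Write a PHYLIP-style lower-triangular distance file."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.groups)}\n")
            for i, g in enumerate(self.groups):
                row = " ".join(f"{self.d[i, j]:.10f}" for j in range(i))
                fh.write(f"{g.replace(' ', '_')} {row}".rstrip() + "\n")

    @classmethod
    def from_csv(cls, path) -> "CranioDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(groups=[str(g) for g in df.index], d=df.to_numpy(dtype=float))


def load_group_means(path, panel: MeasurementPanel | None = None, *,
                     impute: bool = False) -> GroupMeanTable:
    """Load a group-by-measurement CSV/TSV restricted to the panel columns.

    The first column holds group labels; the header must name every panel
    code. Groups with any missing panel cell are excluded (and logged) by
    default, or filled with the column mean when ``impute`` is set.
    """
    panel = panel or MeasurementPanel()
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = [str(c).strip() for c in df.columns]
    missing_codes = [c for c in panel.codes if c not in df.columns]
    if missing_codes:
        raise ValidationError(f"unknown/missing measurement codes: {missing_codes}")
    df = df[list(panel.codes)].apply(pd.to_numeric, errors="coerce")

    excluded: list[str] = []
    if impute:
        df = df.fillna(df.mean(axis=0))
    else:
        bad = df.index[df.isna().any(axis=1)]
        for g in bad:
            log.warning("excluding group %r: missing panel measurements", g)
        excluded = [str(g) for g in bad]
        df = df.drop(index=bad)
    if len(df) < 3:
        raise InsufficientDataError(
            f"need >=3 complete groups for network construction, got {len(df)}")
    return GroupMeanTable(groups=[str(g) for g in df.index], panel=panel,
                          values=df.to_numpy(dtype=float), excluded=excluded)


def qmode_affinity(table: GroupMeanTable) -> AffinityMatrix:
    """Q-mode correlations between groups over z-standardized measurements."""
    x = np.asarray(table.values, dtype=float)
    if np.isnan(x).any():
        raise ValidationError("table contains missing cells; exclude or impute first")
    sd = x.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        codes = [table.panel.codes[i] for i in degenerate]
        raise ValidationError(f"zero-variance measurement column(s): {codes}")
    z = (x - x.mean(axis=0)) / sd
    r = np.corrcoef(z)  # Pearson across measurements, per pair of group profiles
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return AffinityMatrix(groups=list(table.groups), r=r)


def to_distance(aff: AffinityMatrix) -> CranioDistanceMatrix:
    """Elementwise ``d = 1 - r`` with an exactly zero diagonal."""
    d = 1.0 - aff.r
    np.fill_diagonal(d, 0.0)
    return CranioDistanceMatrix(groups=list(aff.groups), d=d)
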