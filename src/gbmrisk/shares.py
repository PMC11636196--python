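"""Market-share disaggregation of a total production series into material forms.

The total production of a material family (here graphene-based
materials: pristine graphene ``pG``, graphene oxide ``GO`` and reduced
graphene oxide ``rGO``) is split into forms with two row-stochastic
matrices: ``E`` (year x product-category market shares) and ``F``
(product-category x form splits).  Their product ``G = E F`` gives the
year x form shares used to scale the total production series, and the
per-form category allocation is obtained by re-weighting ``E`` with the
elements of ``F`` and ``G``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ShareMatrixError

ROW_SUM_TOL = 1e-9

#: Canonical ordered form labels for graphene-based materials.
GBM_FORMS = ("pG", "GO", "rGO")


@dataclass(frozen=True)
class ShareMatrix:
    """Row-stochastic allocation matrix with labelled axes.

    Rows are years or product categories, columns are product categories
    or material forms.  Every row must sum to 1 (within ``tol``) and all
    entries must lie in [0, 1].
    """

    row_labels: tuple
    col_labels: tuple
    values: np.ndarray
    tol: float = ROW_SUM_TOL

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))
        if vals.ndim != 2:
            raise ShareMatrixError("share matrix must be two-dimensional")
        if vals.shape != (len(self.row_labels), len(self.col_labels)):
            raise ShareMatrixError(
                f"shape {vals.shape} does not match labels "
                f"({len(self.row_labels)} rows, {len(self.col_labels)} cols)"
            )
        if np.any(vals < -self.tol) or np.any(vals > 1 + self.tol):
            bad = [self.row_labels[i] for i in
                   np.unique(np.argwhere((vals < -self.tol) | (vals > 1 + self.tol))[:, 0])]
            raise ShareMatrixError(f"entries outside [0, 1] in rows {bad}", rows=bad)
        sums = vals.sum(axis=1)
        off = np.abs(sums - 1.0) > self.tol
        if np.any(off):
            bad = [self.row_labels[i] for i in np.flatnonzero(off)]
            raise ShareMatrixError(
                f"rows {bad} sum to {sums[off]} rather than 1", rows=bad
            )

    @property
    def shape(self):
        return self.values.shape

    def row(self, label) -> np.ndarray:
        return self.values[self.row_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("row").to_csv(path)

    @classmethod
    def from_csv(cls, path, tol: float = ROW_SUM_TOL) -> "ShareMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(float), tol=tol)


@dataclass
class ProductionSeries:
    """Monte-Carlo production (or release) masses per year, in tonnes/year.

    ``samples`` has shape (n_years, n_runs); every year carries the same
    number of runs and all masses are non-negative.
    """

    years: tuple
    samples: np.ndarray
    unit: str = "t/year"

    def __post_init__(self):
        self.years = tuple(self.years)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] != len(self.years):
            raise ShareMatrixError(
                f"{len(self.years)} years but {self.samples.shape[0]} sample rows"
            )
        if np.any(self.samples < 0):
            raise ShareMatrixError("production samples must be non-negative")

    @property
    def n_runs(self) -> int:
        return self.samples.shape[1]

    def for_year(self, year) -> np.ndarray:
        return self.samples[self.years.index(year)]


@dataclass(frozen=True)
class MarketMatrices:
    """Form market fractions ``A`` and form x application distribution ``B``."""

    form_labels: tuple
    application_labels: tuple
    A: np.ndarray  # over forms, sums to 1
    B: np.ndarray  # forms x applications, rows sum to 1

    def __post_init__(self):
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "B", np.asarray(self.B, dtype=float))
        if abs(self.A.sum() - 1.0) > ROW_SUM_TOL:
            raise ShareMatrixError(f"market fractions A sum to {self.A.sum()}, not 1")
        if self.B.shape != (len(self.form_labels), len(self.application_labels)):
            raise ShareMatrixError("B shape does not match form/application labels")
        bad = np.flatnonzero(np.abs(self.B.sum(axis=1) - 1.0) > ROW_SUM_TOL)
        if bad.size:
            rows = [self.form_labels[i] for i in bad]
            raise ShareMatrixError(f"B rows {rows} do not sum to 1", rows=rows)


def compose_form_shares(E: ShareMatrix, F: ShareMatrix) -> ShareMatrix:
    """Year x form shares ``G = E F`` from market shares and form splits.

    ``E`` allocates each year over product categories, ``F`` allocates
    each category over forms; the composition is again row-stochastic.
    """
    if E.col_labels != F.row_labels:
        raise ShareMatrixError(
            f"category labels of E {list(E.col_labels)} do not match "
            f"rows of F {list(F.row_labels)}",
            cols=E.col_labels, rows=F.row_labels,
        )
    return ShareMatrix(E.row_labels, F.col_labels, E.values @ F.values)


def reallocate_categories(E: ShareMatrix, F: ShareMatrix, G: ShareMatrix,
                          form) -> ShareMatrix:
    """Per-form category allocation: entry (year, category) = e * f / g.

    The year-by-category weight of one form is the product of the
    category's market share (``e_mn``) and the form's split within that
    category (``f_nz``), normalised by the form's total yearly share
    ``g_mz`` so rows sum to 1.  Years in which the form has zero share
    are an error: the form was not on the market that year.
    """
    z = _col_index(G, form)
    if F.col_labels != G.col_labels or E.col_labels != F.row_labels:
        raise ShareMatrixError("E, F, G labels are not mutually consistent")
    g = G.values[:, z]
    zero = np.flatnonzero(g <= 0)
    if zero.size:
        years = [G.row_labels[i] for i in zero]
        raise ShareMatrixError(
            f"form {form!r} has zero total share in years {years}; "
            "no category allocation exists", rows=years,
        )
    vals = E.values * F.values[:, z][None, :] / g[:, None]
    return ShareMatrix(E.row_labels, E.col_labels, vals)


def allocate_form_production(P: ProductionSeries, G: ShareMatrix,
                             form) -> ProductionSeries:
    """Scale each year's production samples by that year's form share."""
    z = _col_index(G, form)
    missing = [y for y in P.years if y not in G.row_labels]
    if missing:
        raise ShareMatrixError(f"years {missing} absent from form-share matrix",
                               rows=missing)
    g = np.array([G.values[G.row_labels.index(y), z] for y in P.years])
    return ProductionSeries(P.years, P.samples * g[:, None], unit=P.unit)


def combine_market_matrices(M: MarketMatrices) -> ShareMatrix:
    """Application x form distribution from market fractions A and matrix B.

    The weight of form z within an application is proportional to
    ``A_z * B_z,application``, renormalised per application.
    """
    weights = M.A[:, None] * M.B  # forms x applications
    totals = weights.sum(axis=0)
    dead = np.flatnonzero(totals <= 0)
    if dead.size:
        apps = [M.application_labels[i] for i in dead]
        raise ShareMatrixError(f"applications {apps} receive zero total weight",
                               rows=apps)
    return ShareMatrix(M.application_labels, M.form_labels, (weights / totals).T)


def apply_split_rules(category_spec: Mapping, *,
                      form_labels: Sequence = GBM_FORMS,
                      base_rows: Mapping[str, Sequence[float]] | None = None,
                      ) -> np.ndarray:
    """Build one form-split row from a declarative category rule.

    Supported rules:

    ``explicit``
        ``shares``: list of fractions over ``form_labels`` (must sum to 1).
    ``equal``
        ``forms``: the listed forms each get ``1/k``; others 0.
    ``go_halving``
        ``pg``/``go``: a two-form market split (pristine vs oxide) whose
        oxide share is divided equally between oxide and reduced oxide.
    ``mixture``
        ``components``: list of ``{base, weight}``; the weighted sum of
        named rows from ``base_rows``, weights summing to 1.
    """
    form_labels = tuple(form_labels)
    rule = category_spec.get("rule")
    if rule == "explicit":
        row = np.asarray(category_spec["shares"], dtype=float)
        if row.shape != (len(form_labels),):
            raise ShareMatrixError("explicit shares length does not match forms")
    elif rule == "equal":
        listed = category_spec["forms"]
        unknown = [f for f in listed if f not in form_labels]
        if unknown:
            raise ShareMatrixError(f"unknown forms {unknown} in equal-split rule")
        row = np.zeros(len(form_labels))
        for f in listed:
            row[form_labels.index(f)] = 1.0 / len(listed)
    elif rule == "go_halving":
        a, b = float(category_spec["pg"]), float(category_spec["go"])
        if abs(a + b - 1.0) > ROW_SUM_TOL:
            raise ShareMatrixError(f"go_halving shares {a}+{b} do not sum to 1")
        row = np.zeros(len(form_labels))
        row[form_labels.index("pG")] = a
        row[form_labels.index("GO")] = b / 2
        row[form_labels.index("rGO")] = b / 2
    elif rule == "mixture":
        comps = category_spec["components"]
        wsum = sum(float(c["weight"]) for c in comps)
        if abs(wsum - 1.0) > ROW_SUM_TOL:
            raise ShareMatrixError(f"mixture weights sum to {wsum}, not 1")
        if base_rows is None:
            raise ShareMatrixError("mixture rule requires base_rows")
        row = np.zeros(len(form_labels))
        for c in comps:
            name = c["base"]
            if name not in base_rows:
                raise ShareMatrixError(f"unknown base row {name!r} in mixture")
            row = row + float(c["weight"]) * np.asarray(base_rows[name], dtype=float)
    else:
        raise ShareMatrixError(f"unknown split rule {rule!r}")
    if abs(row.sum() - 1.0) > 1e-9:
        raise ShareMatrixError(f"split row sums to {row.sum()}, not 1")
    return row


# ---------------------------------------------------------------------------
# Shipped default form-split matrix for graphene-based materials.
#
# The printed reference table rounds every percentage to integers; the
# constants below store the exact fractions that restore row sums of 1
# (e.g. composite 81/10/10 is stored as 0.81/0.095/0.095 following the
# oxide-halving structure, drilling fluid 33/33/33 as thirds).  The
# printed rounding is reproduced by :func:`format_split_percent`.
# ---------------------------------------------------------------------------

_COMPOSITE = (Fraction(81, 100), Fraction(19, 200), Fraction(19, 200))
_THIRDS = (Fraction(1, 3), Fraction(1, 3), Fraction(1, 3))

DEFAULT_FORM_SPLITS: dict[str, tuple] = {
    "aerospace_aviation": _COMPOSITE,
    "automotive": (Fraction(77, 100), Fraction(23, 200), Fraction(23, 200)),
    "batteries": (Fraction(57, 100), Fraction(43, 200), Fraction(43, 200)),
    "sporting_goods": _COMPOSITE,
    "wind_turbines": _COMPOSITE,
    "construction": (Fraction(0), Fraction(1, 2), Fraction(1, 2)),
    "drilling_fluid": _THIRDS,
    "electronics": (Fraction(1), Fraction(0), Fraction(0)),
    "filtration": (Fraction(0), Fraction(1, 2), Fraction(1, 2)),
    "medical": _THIRDS,
    "paint_coatings": _THIRDS,
    "textiles": _THIRDS,
    "tire": _THIRDS,
    "research_development": (Fraction(71, 100), Fraction(17, 100), Fraction(12, 100)),
}


def default_form_split_matrix() -> ShareMatrix:
    """The shipped 14-category x 3-form split matrix (exact fractions)."""
    cats = tuple(DEFAULT_FORM_SPLITS)
    vals = np.array([[float(x) for x in DEFAULT_FORM_SPLITS[c]] for c in cats])
    return ShareMatrix(cats, GBM_FORMS, vals)


def format_split_percent(row: Sequence[float]) -> tuple[int, ...]:
    """Integer percentages with half-up rounding, as printed in reports."""
    from decimal import Decimal, ROUND_HALF_UP

    return tuple(int(Decimal(100 * float(x)).quantize(0, rounding=ROUND_HALF_UP))
                 for x in row)


def _col_index(m: ShareMatrix, form) -> int:
    if form not in m.col_labels:
        raise ShareMatrixError(
            f"form {form!r} not among columns {list(m.col_labels)}", cols=[form]
        )
    return m.col_labels.index(form)
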