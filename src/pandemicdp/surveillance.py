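"""Flat Laplace sanitization of multi-way case-count tables.

The release pipeline: add independent Laplace(0, m/eps) noise to every
cell of a contingency table (l1 sensitivity 1 under unbounded DP),
repair negative cells (truncate to 0, or redraw until nonnegative),
and — when the grand total n is public knowledge — rescale each
release to sum to n, with largest-remainder rounding so integer
releases conserve the total exactly.

Utility of the sanitized tables is assessed with Poisson log-linear
models fitted per release and pooled with the multiple-synthesis rule.
The module also provides the 2x2x2 multinomial generator used in the
simulation study of this pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dp_core import BudgetLedger, PrivacyBudget, draw_laplace_noise

__all__ = [
    "CellTable",
    "SanitizedTableSet",
    "LogLinearFit",
    "largest_remainder_round",
    "sanitize_table",
    "marginalize",
    "fit_loglinear",
    "simulate_loglinear_counts",
]


@dataclass(frozen=True)
class CellTable:
    """A multi-way contingency table in flattened form.

    ``factors`` is an ordered tuple of (name, levels) pairs; ``counts``
    holds the K = prod(len(levels)) cell counts in C order (the last
    factor varies fastest).
    """

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    counts: np.ndarray
    total_is_public: bool = True

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float).ravel()
        k_expected = int(np.prod([len(lv) for _, lv in self.factors]))
        if counts.size != k_expected:
            raise ValueError(
                f"expected {k_expected} cells for the factor grid, "
                f"got {counts.size}"
            )
        if np.any(counts < 0):
            raise ValueError("cell counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(lv) for _, lv in self.factors)

    @property
    def k(self) -> int:
        return self.counts.size

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    def to_dataframe(self, count_col: str = "count") -> pd.DataFrame:
        grid = list(itertools.product(*(lv for _, lv in self.factors)))
        df = pd.DataFrame(grid, columns=list(self.factor_names))
        df[count_col] = self.counts
        return df

    def marginalize(self, keep_dims) -> "CellTable":
        """Sum over the factors not named in ``keep_dims``."""
        keep = _resolve_dims(self.factor_names, keep_dims)
        arr = self.counts.reshape(self.shape)
        drop = tuple(i for i in range(len(self.factors)) if i not in keep)
        marg = arr.sum(axis=drop) if drop else arr
        factors = tuple(self.factors[i] for i in keep)
        return CellTable(factors=factors, counts=marg.ravel(),
                         total_is_public=self.total_is_public)


def _resolve_dims(names: tuple[str, ...], keep_dims) -> tuple[int, ...]:
    if isinstance(keep_dims, (str, int)):
        keep_dims = [keep_dims]
    keep = []
    for d in keep_dims:
        if isinstance(d, str):
            if d not in names:
                raise ValueError(f"unknown factor {d!r}")
            keep.append(names.index(d))
        else:
            if not 0 <= d < len(names):
                raise ValueError(f"factor index {d} out of range")
            keep.append(int(d))
    if not keep:
        raise ValueError("keep_dims must name at least one factor")
    return tuple(sorted(set(keep)))


@dataclass
class SanitizedTableSet:
    """m sanitized versions of one table, plus provenance."""

    factors: tuple[tuple[str, tuple[str, ...]], ...]
    releases: list[np.ndarray]
    budget: PrivacyBudget
    postprocessing: dict = field(default_factory=dict)
    ledger: BudgetLedger | None = None

    @property
    def m(self) -> int:
        return len(self.releases)

    def release_table(self, l: int) -> CellTable:
        return CellTable(factors=self.factors, counts=self.releases[l],
                         total_is_public=False)


def largest_remainder_round(values, total: int) -> np.ndarray:
    """Round nonnegative reals to integers summing exactly to ``total``.

    Largest-remainder (Hamilton) apportionment: floor every value, then
    hand the missing units to the largest fractional parts.  Ties break
    by cell index (deterministic).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be nonnegative")
    if values.sum() <= 0:
        raise ValueError("values must have a positive sum")
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(np.int64)
    deficit = int(round(total - floors.sum()))
    if deficit > 0:
        # stable argsort on negated remainders -> ties broken by index
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:deficit]] += 1
    return floors


def sanitize_table(
    table: CellTable,
    budget: PrivacyBudget,
    rng: np.random.Generator,
    negatives: str = "truncate",
    normalize: bool = True,
    round_counts: bool = True,
    sensitivity: float = 1.0,
    max_retries: int = 100,
) -> SanitizedTableSet:
    """Flat Laplace sanitizer: noise every cell, m independent times.

    Each release spends eps_total/m; the per-cell noise scale is
    sensitivity * m / eps_total.  With ``negatives="truncate"``
    negative cells are set to 0; ``"resample"`` redraws each offending
    cell until nonnegative.  With ``normalize`` (requires a public
    total) each release is rescaled to sum to n, and with
    ``round_counts`` additionally rounded by largest remainder so the
    total is conserved exactly.
    """
    if negatives not in ("truncate", "resample"):
        raise ValueError("negatives must be 'truncate' or 'resample'")
    if normalize and not table.total_is_public:
        raise ValueError("normalization requires a public total")
    eps_release = budget.per_release
    scale = sensitivity / eps_release
    n_public = int(round(table.total))
    ledger = BudgetLedger(budget.epsilon_total)

    releases: list[np.ndarray] = []
    for l in range(budget.m):
        ledger.spend(f"release-{l}", eps_release)
        for _attempt in range(max_retries):
            noisy = table.counts + draw_laplace_noise(scale, table.k, rng)
            if negatives == "truncate":
                noisy = np.maximum(noisy, 0.0)
            else:
                bad = noisy < 0
                while bad.any():
                    noisy[bad] = table.counts[bad] + draw_laplace_noise(
                        scale, int(bad.sum()), rng
                    )
                    bad = noisy < 0
            if not normalize:
                break
            if noisy.sum() > 0:  # degenerate all-zero release: retry
                break
        else:
            raise RuntimeError(
                "sanitized table summed to zero in every retry; "
                "epsilon is likely far too small for this table"
            )
        if normalize:
            if round_counts:
                noisy = largest_remainder_round(noisy, n_public).astype(float)
            else:
                noisy = noisy * (n_public / noisy.sum())
        elif round_counts:
            noisy = np.round(noisy)
        releases.append(noisy)

    return SanitizedTableSet(
        factors=table.factors,
        releases=releases,
        budget=budget,
        postprocessing={
            "negatives": negatives,
            "normalize": normalize,
            "round_counts": round_counts,
            "sensitivity": sensitivity,
        },
        ledger=ledger,
    )


def marginalize(sanitized: SanitizedTableSet, keep_dims) -> SanitizedTableSet:
    """Sum sanitized cells over dropped factors, within each release.

    Post-processing only (no extra privacy cost).  A summed cell
    carries the *sum* of the component noise variances; the extra
    sanitization variability is inherited, not removed.
    """
    names = tuple(name for name, _ in sanitized.factors)
    keep = _resolve_dims(names, keep_dims)
    shape = tuple(len(lv) for _, lv in sanitized.factors)
    drop = tuple(i for i in range(len(shape)) if i not in keep)
    new_releases = []
    for rel in sanitized.releases:
        arr = rel.reshape(shape)
        new_releases.append((arr.sum(axis=drop) if drop else arr).ravel())
    return SanitizedTableSet(
        factors=tuple(sanitized.factors[i] for i in keep),
        releases=new_releases,
        budget=sanitized.budget,
        postprocessing={**sanitized.postprocessing, "marginalized_to": names},
        ledger=sanitized.ledger,
    )


@dataclass(frozen=True)
class LogLinearFit:
    """Poisson log-linear regression result."""

    coefficients: np.ndarray
    vcov: np.ndarray
    se: np.ndarray
    term_names: tuple[str, ...]
    deviance: float


def _build_design(
    table: CellTable, model_terms
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Treatment-coded design matrix for main effects and interactions."""
    df = table.to_dataframe()
    names = table.factor_names
    # dummy-code each factor once, reference = first level
    dummies: dict[str, pd.DataFrame] = {}
    for name, levels in table.factors:
        cols = {}
        for lev in levels[1:]:
            cols[f"{name}[{lev}]"] = (df[name] == lev).astype(float)
        dummies[name] = pd.DataFrame(cols)

    columns = [np.ones(table.k)]
    colnames = ["Intercept"]
    for term in model_terms:
        parts = (term,) if isinstance(term, str) else tuple(term)
        for p in parts:
            if p not in names:
                raise ValueError(f"unknown factor {p!r} in model term {term!r}")
        blocks = [dummies[p] for p in parts]
        for combo in itertools.product(*(b.columns for b in blocks)):
            col = np.ones(table.k)
            for b, c in zip(blocks, combo):
                col = col * b[c].to_numpy()
            columns.append(col)
            colnames.append(":".join(combo))
    X = np.column_stack(columns)

    # incremental rank check so the offending term can be named
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            raise ValueError(
                f"design matrix is rank deficient: column {colnames[j]!r} "
                "is collinear with preceding terms"
            )
        rank = new_rank
    return X, tuple(colnames)


def fit_loglinear(table: CellTable, model_terms=None) -> LogLinearFit:
    """Fit a Poisson log-linear model to (possibly non-integer) counts.

    ``model_terms`` is a list of factor names and tuples of factor
    names (interactions); default: all main effects.  Sanitized,
    normalized counts need not be integers — the Poisson quasi-score
    only uses the mean model, so real-valued counts are accepted as-is.
    """
    if model_terms is None:
        model_terms = list(table.factor_names)
    counts = table.counts
    if counts.sum() == 0:
        raise ValueError("cannot fit a log-linear model to an all-zero table")
    X, colnames = _build_design(table, model_terms)
    model = sm.GLM(counts, X, family=sm.families.Poisson())
    res = model.fit()
    params = np.asarray(res.params, dtype=float)
    vcov = np.asarray(res.cov_params(), dtype=float)
    return LogLinearFit(
        coefficients=params,
        vcov=vcov,
        se=np.sqrt(np.diag(vcov)),
        term_names=colnames,
        deviance=float(res.deviance),
    )


def simulate_loglinear_counts(
    beta, n: int, rng: np.random.Generator
) -> CellTable:
    """Draw a 2x2x2 table of counts from a log-linear multinomial model.

    Cell rates follow log(lambda_k) = b0 + b1 x1 + b2 x2 + b3 x3
    + b4 x1 x2 + b5 x1 x3 + b6 x2 x3 over the 8 binary-factor cells;
    the n observations are allocated multinomially with probabilities
    p_k proportional to lambda_k.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (7,):
        raise ValueError("beta must be a 7-vector")
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    cells = np.array(list(itertools.product((0, 1), repeat=3)), dtype=float)
    x1, x2, x3 = cells.T
    log_lam = (
        beta[0] + beta[1] * x1 + beta[2] * x2 + beta[3] * x3
        + beta[4] * x1 * x2 + beta[5] * x1 * x3 + beta[6] * x2 * x3
    )
    lam = np.exp(log_lam)
    p = lam / lam.sum()
    counts = rng.multinomial(int(n), p)
    factors = (
        ("x1", ("0", "1")),
        ("x2", ("0", "1")),
        ("x3", ("0", "1")),
    )
    return CellTable(factors=factors, counts=counts.astype(float))
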