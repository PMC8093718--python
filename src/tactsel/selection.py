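"""Phenotypic selection analysis for two alternative reproductive tactics.

Lande-Arnold style estimation on relative fitness: selection differentials
(one trait at a time, with tactic and tactic-by-trait interaction), linear
gradients (all traits jointly, linear terms only), and quadratic gradients
(linear + squared terms, quadratic estimates doubled for reporting).
Significance comes from a permutation null in which relative fitness is
shuffled across the whole male population while traits and tactic labels
stay attached to individuals.  The default p-value is the two-sided
exceedance count #{|pseudo-estimate| >= |estimate|} / n_perm, which is
exactly calibrated by exchangeability whatever the shape of the null;
``p_method="directional"`` instead counts exceedances in the tail picked by
the observed sign (the recipe common in selection studies), which for a
symmetric null doubles the type-I rate at a given alpha and is provided for
comparability, not as the inferential default.

Tactic ("ART") coding defaults to sum-to-zero contrasts (courter +1/2,
sneaker -1/2), so a trait's main effect is the across-tactic average slope
-- a significant average slope means at least one tactic is off its fitness
optimum -- while the interaction is the slope difference between tactics --
significance there means the tactics have different optima.  Together these
are the two operational criteria for intralocus tactical conflict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TACTICS

__all__ = [
    "prepare",
    "SelectionFit",
    "selection_differential",
    "linear_gradients",
    "quadratic_gradients",
    "permutation_p",
    "iatc_verdict",
]

_ART_CODES = {
    "sum": {"courter": 0.5, "sneaker": -0.5},
    "treatment": {"courter": 1.0, "sneaker": 0.0},
}


def prepare(
    traits: pd.DataFrame,
    fitness: pd.DataFrame | None = None,
    trait_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Attach relative fitness and population-standardized traits.

    ``traits`` needs columns id, tactic and the trait columns; absolute
    fitness (offspring counts) is taken from its ``n_offspring`` column or
    merged in from ``fitness`` (id, n_offspring).  Zero-fitness males are
    retained -- they carry real information about selection.  Relative
    fitness w = W / mean(W) and z-scores use moments over ALL males.
    """
    df = traits.copy()
    if fitness is not None:
        df = df.drop(columns=["n_offspring"], errors="ignore").merge(
            fitness[["id", "n_offspring"]], on="id", how="left", validate="1:1"
        )
        if df["n_offspring"].isna().any():
            missing = df.loc[df["n_offspring"].isna(), "id"].tolist()
            raise ValueError(f"males without a fitness record: {missing[:5]}")
    if "n_offspring" not in df.columns:
        raise ValueError("no absolute fitness column (n_offspring)")
    if trait_cols is None:
        trait_cols = [
            c for c in df.columns
            if c not in ("id", "tactic", "n_offspring")
            and pd.api.types.is_numeric_dtype(df[c])
            and not pd.api.types.is_bool_dtype(df[c])
        ]
    w_abs = df["n_offspring"].to_numpy(dtype=float)
    if np.any(w_abs < 0):
        raise ValueError("negative offspring counts")
    mean_w = w_abs.mean()
    if mean_w <= 0:
        raise ValueError("population mean fitness is zero; nothing to analyze")
    df["w"] = w_abs / mean_w
    for col in trait_cols:
        x = df[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"trait {col} has zero variance; cannot standardize")
        df[f"z_{col}"] = (x - x.mean()) / sd
    df.attrs["trait_cols"] = list(trait_cols)
    return df


# ---------------------------------------------------------------------------
# OLS + permutation engine


def _check_design(x: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"singular design matrix (terms: {names})")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """(coefficients, residual SS, diag of (X'X)^-1)."""
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    return beta, float(resid @ resid), np.diag(xtx_inv)


def _permuted_coefs(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    seed: int,
    chunk: int = 2_000,
) -> np.ndarray:
    """Coefficient pseudo-estimates under the fitness-shuffle null,
    shape (p, n_perm)."""
    rng = np.random.default_rng(seed)
    pinv = np.linalg.pinv(x)
    n = len(y)
    out = np.empty((x.shape[1], n_perm))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perm_y = np.empty((n, b))
        for j in range(b):
            perm_y[:, j] = y[rng.permutation(n)]
        out[:, done:done + b] = pinv @ perm_y
        done += b
    return out


def _perm_pvalue(
    obs: float,
    null: np.ndarray,
    plus_one: bool = False,
    method: str = "two_sided",
) -> float:
    """Permutation p from a vector of pseudo-estimates; ties count as
    exceeding (conservative).

    two_sided: #{|null| >= |obs|} / m -- exact by exchangeability.
    directional: exceedances in the tail given by the observed sign; a zero
    observed estimate falls back to the two-sided count.
    """
    m = len(null)
    if method == "two_sided" or obs == 0:
        b = int(np.sum(np.abs(null) >= abs(obs) - 1e-15))
    elif method == "directional":
        if obs > 0:
            b = int(np.sum(null >= obs - 1e-15))
        else:
            b = int(np.sum(null <= obs + 1e-15))
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return (b + 1) / (m + 1) if plus_one else b / m


def permutation_p(
    x: np.ndarray,
    y: np.ndarray,
    coef_index: int,
    n_perm: int = 9_999,
    seed: int = 0,
    plus_one: bool = False,
    p_method: str = "two_sided",
) -> float:
    """Permutation p-value for one coefficient of the OLS of y on x, under
    the shuffle-y null.  Seed-reproducible."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, _, _ = _ols(x, y)
    null = _permuted_coefs(x, y, n_perm, seed)[coef_index]
    return _perm_pvalue(float(beta[coef_index]), null, plus_one, p_method)


@dataclass
class SelectionFit:
    """One fitted selection model: per-term estimates (quadratic terms
    already doubled in ``estimate``), partial SS, F, and permutation p;
    optional per-tactic follow-up tables."""

    kind: str  # differential | linear_gradient | quadratic_gradient
    terms: pd.DataFrame
    per_art: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_perm: int = 0
    seed: int = 0
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)

    def p_for(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["perm_p"].iloc[0])

    def estimate_for(self, term: str) -> float:
        row = self.terms.loc[self.terms["term"] == term]
        if row.empty:
            raise KeyError(term)
        return float(row["estimate"].iloc[0])


def _fit_terms(
    x: np.ndarray,
    y: np.ndarray,
    names: list[str],
    perm_terms: list[str],
    n_perm: int,
    seed: int,
    plus_one: bool,
    double_terms: set[str] = frozenset(),
    p_method: str = "two_sided",
) -> pd.DataFrame:
    """Shared fit + permutation machinery.

    Permutation tests are computed on the *fitted* coefficients; terms in
    ``double_terms`` have their reported estimate doubled afterwards (the
    quadratic reporting convention).
    """
    _check_design(x, names)
    n, p = x.shape
    beta, rss, cjj = _ols(x, y)
    mse = rss / (n - p) if n > p else math.nan
    null = (
        _permuted_coefs(x, y, n_perm, seed) if n_perm > 0 else None
    )
    rows = []
    for j, name in enumerate(names):
        est = float(beta[j])
        ss = est**2 / cjj[j]
        f = ss / mse if (mse and not math.isnan(mse) and mse > 0) else math.nan
        pp = (
            _perm_pvalue(est, null[j], plus_one, p_method)
            if (null is not None and name in perm_terms)
            else math.nan
        )
        rows.append(
            {
                "term": name,
                "estimate": 2.0 * est if name in double_terms else est,
                "SS": ss,
                "F": f,
                "perm_p": pp,
            }
        )
    return pd.DataFrame(rows)


def _design(
    table: pd.DataFrame,
    traits: list[str],
    quadratic: bool,
    coding: str,
    correlational: bool = False,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    codes = _ART_CODES[coding]
    art = table["tactic"].map(codes)
    if art.isna().any():
        bad = sorted(set(table.loc[art.isna(), "tactic"]))
        raise ValueError(f"unknown tactic labels: {bad}")
    art = art.to_numpy(dtype=float)
    cols = [np.ones(len(table))]
    names = ["intercept"]
    for t in traits:
        cols.append(table[f"z_{t}"].to_numpy(dtype=float))
        names.append(t)
    if quadratic:
        for t in traits:
            cols.append(table[f"z_{t}"].to_numpy(dtype=float) ** 2)
            names.append(f"{t}^2")
        if correlational:
            for i, a in enumerate(traits):
                for b in traits[i + 1:]:
                    cols.append(
                        table[f"z_{a}"].to_numpy(float)
                        * table[f"z_{b}"].to_numpy(float)
                    )
                    names.append(f"{a}:{b}")
    cols.append(art)
    names.append("ART")
    for t in traits:
        cols.append(table[f"z_{t}"].to_numpy(dtype=float) * art)
        names.append(f"ART:{t}")
    if quadratic:
        for t in traits:
            cols.append(table[f"z_{t}"].to_numpy(dtype=float) ** 2 * art)
            names.append(f"ART:{t}^2")
    y = table["w"].to_numpy(dtype=float)
    return np.column_stack(cols), names, y


def _per_art_followups(
    table: pd.DataFrame,
    traits: list[str],
    n_perm: int,
    seed: int,
    plus_one: bool,
    within_tactic_z: bool,
    quadratic: bool = False,
    p_method: str = "two_sided",
) -> dict[str, pd.DataFrame]:
    """Separate per-tactic models (w stays population-relative).

    ``within_tactic_z`` re-standardizes traits inside each tactic so the
    slope is on the tactic's own trait scale; default keeps population z.
    """
    out = {}
    for t_index, tactic in enumerate(TACTICS):
        sub = table[table["tactic"] == tactic]
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 males in tactic {tactic}")
        cols = [np.ones(len(sub))]
        names = ["intercept"]
        for t in traits:
            z = sub[f"z_{t}"].to_numpy(dtype=float)
            if within_tactic_z:
                sd = z.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"{t} constant within {tactic}")
                z = (z - z.mean()) / sd
            cols.append(z)
            names.append(t)
        double: set[str] = set()
        if quadratic:
            for t, zcol in zip(traits, list(cols[1:1 + len(traits)])):
                cols.append(zcol**2)
                names.append(f"{t}^2")
                double.add(f"{t}^2")
        x = np.column_stack(cols)
        y = sub["w"].to_numpy(dtype=float)
        out[tactic] = _fit_terms(
            x, y, names,
            perm_terms=[n for n in names if n != "intercept"],
            n_perm=n_perm, seed=seed + 101 * (t_index + 1),
            plus_one=plus_one, double_terms=double, p_method=p_method,
        )
    return out


def selection_differential(
    table: pd.DataFrame,
    trait: str,
    n_perm: int = 9_999,
    seed: int = 0,
    alpha: float = 0.05,
    coding: str = "sum",
    within_tactic_z: bool = False,
    plus_one: bool = False,
    p_method: str = "two_sided",
) -> SelectionFit:
    """Selection differential: w regressed on one standardized trait, with
    tactic and the tactic-by-trait interaction.  The reported s is the trait
    main effect (across-tactic average slope under sum coding).  Per-tactic
    follow-up models are fitted when the interaction is significant."""
    _require_tactic_counts(table)
    x, names, y = _design(table, [trait], quadratic=False, coding=coding)
    terms = _fit_terms(
        x, y, names, perm_terms=[trait, f"ART:{trait}"],
        n_perm=n_perm, seed=seed, plus_one=plus_one, p_method=p_method,
    )
    fit = SelectionFit(
        kind="differential", terms=terms, n_perm=n_perm, seed=seed, alpha=alpha
    )
    if fit.p_for(f"ART:{trait}") < alpha:
        fit.per_art = _per_art_followups(
            table, [trait], n_perm, seed + 1, plus_one, within_tactic_z,
            p_method=p_method,
        )
    return fit


def linear_gradients(
    table: pd.DataFrame,
    traits: list[str],
    n_perm: int = 9_999,
    seed: int = 0,
    alpha: float = 0.05,
    coding: str = "sum",
    within_tactic_z: bool = False,
    plus_one: bool = False,
    p_method: str = "two_sided",
) -> SelectionFit:
    """Linear (directional) selection gradients beta: multiple regression of
    w on all standardized traits plus tactic and tactic-by-trait
    interactions; no quadratic terms (they would contaminate beta when the
    traits are not multivariate normal)."""
    _require_tactic_counts(table)
    x, names, y = _design(table, traits, quadratic=False, coding=coding)
    perm_terms = traits + [f"ART:{t}" for t in traits]
    terms = _fit_terms(x, y, names, perm_terms, n_perm, seed, plus_one,
                       p_method=p_method)
    fit = SelectionFit(
        kind="linear_gradient", terms=terms, n_perm=n_perm, seed=seed,
        alpha=alpha,
    )
    if any(fit.p_for(f"ART:{t}") < alpha for t in traits):
        fit.per_art = _per_art_followups(
            table, traits, n_perm, seed + 1, plus_one, within_tactic_z,
            p_method=p_method,
        )
    return fit


def quadratic_gradients(
    table: pd.DataFrame,
    traits: list[str],
    n_perm: int = 9_999,
    seed: int = 0,
    alpha: float = 0.05,
    coding: str = "sum",
    within_tactic_z: bool = False,
    plus_one: bool = False,
    correlational: bool = False,
    p_method: str = "two_sided",
) -> SelectionFit:
    """Quadratic (stabilizing/disruptive) gradients gamma_ii: w on linear +
    squared standardized traits with tactic interactions.  Reported
    quadratic estimates are DOUBLED (regression halves the curvature of the
    fitness surface); permutation p-values are computed on the fitted,
    undoubled coefficients -- doubling is a reporting transform only.
    Cross-product (correlational) terms are off by default."""
    _require_tactic_counts(table)
    x, names, y = _design(
        table, traits, quadratic=True, coding=coding,
        correlational=correlational,
    )
    sq = {f"{t}^2" for t in traits}
    if correlational:
        sq |= {
            f"{a}:{b}" for i, a in enumerate(traits) for b in traits[i + 1:]
        }
    perm_terms = [n for n in names if n not in ("intercept", "ART")]
    terms = _fit_terms(
        x, y, names, perm_terms, n_perm, seed, plus_one,
        double_terms=sq | {f"ART:{t}^2" for t in traits}, p_method=p_method,
    )
    fit = SelectionFit(
        kind="quadratic_gradient", terms=terms, n_perm=n_perm, seed=seed,
        alpha=alpha,
    )
    interactions = [f"ART:{t}" for t in traits] + [f"ART:{t}^2" for t in traits]
    if any(fit.p_for(i) < alpha for i in interactions):
        fit.per_art = _per_art_followups(
            table, traits, n_perm, seed + 1, plus_one, within_tactic_z,
            quadratic=True, p_method=p_method,
        )
    return fit


def _require_tactic_counts(table: pd.DataFrame, minimum: int = 3) -> None:
    counts = table["tactic"].value_counts()
    for tactic in TACTICS:
        if counts.get(tactic, 0) < minimum:
            raise ValueError(
                f"fewer than {minimum} males in tactic {tactic}"
            )


def iatc_verdict(
    fits: dict[str, SelectionFit], alpha: float = 0.05
) -> pd.DataFrame:
    """Two-criterion intralocus-tactical-conflict verdict per trait.

    optimum_differs: the tactic-by-trait interaction is significant (the
    tactics have different optima).  off_optimum: the overall trait term is
    significant (at least one tactic is not at its optimum).  Per-tactic
    directions report the sign of the per-tactic differential when the
    follow-up model was fitted and significant, else 'ns'.
    """
    rows = []
    for trait, fit in fits.items():
        inter_p = fit.p_for(f"ART:{trait}")
        overall_p = fit.p_for(trait)
        row = {
            "trait": trait,
            "optimum_differs": bool(inter_p < alpha),
            "off_optimum": bool(overall_p < alpha),
            "interaction_p": inter_p,
            "overall_p": overall_p,
        }
        for tactic in TACTICS:
            direction = "ns"
            if fit.per_art and tactic in fit.per_art:
                sub = fit.per_art[tactic]
                r = sub.loc[sub["term"] == trait]
                if not r.empty and float(r["perm_p"].iloc[0]) < alpha:
                    direction = "+" if float(r["estimate"].iloc[0]) > 0 else "-"
            row[f"direction_{tactic}"] = direction
        rows.append(row)
    return pd.DataFrame(rows)
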