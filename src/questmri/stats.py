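"""Group statistics for the quench comparison and HO-1 intensities.

The QUEST readout is a pattern across three groups, compared within the
unprotected ear: noise exposure elevates cochlear R1 above the normal-hearing
level, and acute anti-oxidant administration "quenches" it back — NE > NH,
NE+AO < NE, NE+AO indistinguishable from NH.  The omnibus test is a two-way
ANOVA with treatment and ear as factors (Type II sums of squares for the
unbalanced 11/11/8 design) followed by Scheffé post hoc contrasts; planned
(unadjusted) contrasts are available as an alternative.

HO-1 immunofluorescence percent changes are analysed with a mixed-factor
ANOVA: random intercepts per rat and separate residual variances for the
two ears, fitted by REML, with least-squares-means pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

DEFAULT_ALPHA = 0.05  # p <= alpha counts as significant

EXPECTED_GROUPS = ("NH", "NE", "NE+AO")


def _validate_group_table(table: pd.DataFrame) -> None:
    required = {"subject", "group", "ear", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    dup = table.duplicated(["subject", "ear"])
    if dup.any():
        raise ValueError("each (subject, ear) may appear at most once")
    counts = table.groupby("group")["subject"].nunique()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 subjects: {small}")


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-factor F tests plus the residual mean square used by post hocs."""

    table: pd.DataFrame          # index: factor; columns F, df, p
    mse: float
    df_resid: int
    cell_means: pd.DataFrame

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])


def two_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Treatment x ear ANOVA (Type II sums of squares, unbalanced-safe)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    _validate_group_table(table)
    if table["ear"].nunique() < 2:
        raise ValueError("both ears must be represented")
    if table["group"].nunique() < 2:
        raise ValueError("at least two groups are required")
    cells = table.groupby(["group", "ear"], observed=True)["value"]
    sizes = cells.size()
    full_index = pd.MultiIndex.from_product(
        [table["group"].unique(), table["ear"].unique()])
    for cell in full_index:
        if cell not in sizes.index or sizes[cell] == 0:
            raise ValueError(f"empty design cell: group={cell[0]!r}, ear={cell[1]!r}")

    model = smf.ols("value ~ C(group) * C(ear)", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    out = pd.DataFrame({
        "F": [aov.loc["C(group)", "F"], aov.loc["C(ear)", "F"],
              aov.loc["C(group):C(ear)", "F"]],
        "df": [aov.loc["C(group)", "df"], aov.loc["C(ear)", "df"],
               aov.loc["C(group):C(ear)", "df"]],
        "p": [aov.loc["C(group)", "PR(>F)"], aov.loc["C(ear)", "PR(>F)"],
              aov.loc["C(group):C(ear)", "PR(>F)"]],
    }, index=["treatment", "ear", "interaction"])
    mse = float(aov.loc["Residual", "sum_sq"] / aov.loc["Residual", "df"])
    cell_means = cells.agg(["mean", "count"]).reset_index()
    return AnovaResult(out, mse, int(aov.loc["Residual", "df"]), cell_means)


def _cell(table: pd.DataFrame, group: str, ear: str) -> np.ndarray:
    values = table.query("group == @group and ear == @ear")["value"].to_numpy()
    if values.size == 0:
        raise ValueError(f"empty design cell: group={group!r}, ear={ear!r}")
    return values


def scheffe_contrast(table: pd.DataFrame, pair: tuple[str, str], ear: str,
                     anova: AnovaResult | None = None) -> tuple[float, float]:
    """Scheffé-adjusted pairwise group contrast within one ear level.

    The estimate is ``mean(pair[0]) - mean(pair[1])``; the Scheffé family is
    the set of contrasts among the treatment-group means, so the statistic
    ``t^2 / (k - 1)`` is referred to ``F(k - 1, df_resid)`` with ``k`` the
    number of treatment groups and the residual mean square taken from the
    two-way ANOVA.
    """
    anova = anova or two_way_anova(table)
    k = table["group"].nunique()
    x1, x2 = (_cell(table, g, ear) for g in pair)
    estimate = float(x1.mean() - x2.mean())
    se2 = anova.mse * (1.0 / x1.size + 1.0 / x2.size)
    f_stat = estimate ** 2 / se2 / (k - 1)
    p = float(sps.f.sf(f_stat, k - 1, anova.df_resid))
    return estimate, p


def planned_contrast(table: pd.DataFrame, pair: tuple[str, str], ear: str,
                     anova: AnovaResult | None = None) -> tuple[float, float]:
    """Unadjusted two-sided t contrast using the same pooled residual MS."""
    anova = anova or two_way_anova(table)
    x1, x2 = (_cell(table, g, ear) for g in pair)
    estimate = float(x1.mean() - x2.mean())
    se = np.sqrt(anova.mse * (1.0 / x1.size + 1.0 / x2.size))
    t = estimate / se
    p = float(2 * sps.t.sf(abs(t), anova.df_resid))
    return estimate, p


# ---------------------------------------------------------------------------
# the quench assessment
# ---------------------------------------------------------------------------

@dataclass
class QuestOutcome:
    """Decision pattern for the quench-assisted comparison."""

    elevated: bool               # NE unprotected above NH unprotected
    quenched: bool               # NE+AO below NE, and not different from NH
    contrasts: list              # (pair, ear, estimate, p)
    anova: AnovaResult
    alpha: float

    def to_dict(self) -> dict:
        return {
            "elevated": bool(self.elevated),
            "quenched": bool(self.quenched),
            "alpha": self.alpha,
            "contrasts": [
                {"pair": list(pair), "ear": ear, "estimate": est, "p": p}
                for pair, ear, est, p in self.contrasts
            ],
            "anova": {
                factor: {"F": float(row["F"]), "df": float(row["df"]),
                         "p": float(row["p"])}
                for factor, row in self.anova.table.iterrows()
            },
        }


def quest_assess(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                 method: str = "scheffe") -> QuestOutcome:
    """Assess elevation and quench on the unprotected-ear R1 values.

    ``elevated``: NE exceeds NH at ``alpha``.  ``quenched``: NE+AO is below
    NE at ``alpha`` *and* NE+AO does not differ from NH (p > alpha).
    ``method`` selects "scheffe" (default) or "planned" contrasts.
    """
    missing = set(EXPECTED_GROUPS) - set(table["group"].unique())
    if missing:
        raise ValueError(f"missing groups: {sorted(missing)}")
    contrast = {"scheffe": scheffe_contrast, "planned": planned_contrast}[method]
    anova = two_way_anova(table)
    pairs = [("NE", "NH"), ("NE+AO", "NE"), ("NE+AO", "NH")]
    results = []
    for pair in pairs:
        est, p = contrast(table, pair, "unprotected", anova)
        results.append((pair, "unprotected", est, p))
    (_, _, est_ne_nh, p_ne_nh) = results[0]
    (_, _, est_ao_ne, p_ao_ne) = results[1]
    (_, _, _, p_ao_nh) = results[2]
    elevated = est_ne_nh > 0 and p_ne_nh <= alpha
    quenched = est_ao_ne < 0 and p_ao_ne <= alpha and p_ao_nh > alpha
    return QuestOutcome(elevated, quenched, results, anova, alpha)


# ---------------------------------------------------------------------------
# percent change
# ---------------------------------------------------------------------------

def percent_change(signal, background):
    """100 * (signal - background) / background; background must be > 0."""
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValueError("background intensity must be positive")
    out = 100.0 * (signal - background) / background
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# heteroscedastic mixed-factor ANOVA (random rat intercepts, per-ear
# residual variances, REML)
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    treatment_F: float
    df_num: int
    df_den: int
    p: float
    lsmeans: pd.DataFrame        # group, lsmean, se
    pairwise: pd.DataFrame       # group1, group2, estimate, se, t, p
    sigma2_rat: float
    sigma2_ear: dict             # ear level -> residual variance
    beta: np.ndarray
    reml: float


def _mixed_design(records: pd.DataFrame):
    groups = sorted(records["group"].unique())
    ears = sorted(records["ear"].unique())
    n = len(records)
    # fixed effects: intercept, group dummies (ref = groups[0]), ear dummies
    p = 1 + (len(groups) - 1) + (len(ears) - 1)
    X = np.zeros((n, p))
    X[:, 0] = 1.0
    for j, g in enumerate(groups[1:], start=1):
        X[:, j] = (records["group"] == g).to_numpy(dtype=float)
    for j, e in enumerate(ears[1:], start=len(groups)):
        X[:, j] = (records["ear"] == e).to_numpy(dtype=float)
    ear_idx = records["ear"].map({e: i for i, e in enumerate(ears)}).to_numpy()
    return X, groups, ears, ear_idx


def mixed_anova_ho1(records: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                    value_col: str = "value") -> MixedAnovaResult:
    """Mixed-factor ANOVA for per-image HO-1 percent changes.

    Model: value = treatment + ear + rat-intercept + error, where the rat
    intercept is a random effect and the residual variance differs between
    ears.  Fitted by REML with the left-ear-relative variance ratios
    profiled over a 2-D simplex search.  The treatment F test uses
    between-rat denominator degrees of freedom (n_rats - n_groups), and
    pairwise least-squares-means comparisons average over ears.
    """
    required = {"rat", "group", "ear", value_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rat_counts = records.groupby("group")["rat"].nunique()
    if (rat_counts < 2).any():
        bad = rat_counts[rat_counts < 2].index.tolist()
        raise ValueError(
            f"groups with a single rat (random intercept inestimable): {bad}")

    records = records.reset_index(drop=True)
    y = records[value_col].to_numpy(dtype=float)
    X, groups, ears, ear_idx = _mixed_design(records)
    n, p = X.shape
    rat_ids = records["rat"].to_numpy()
    rat_blocks = [np.flatnonzero(rat_ids == r) for r in pd.unique(rat_ids)]
    n_rats = len(rat_blocks)

    def profile(theta):
        """Profiled -2 REML log-likelihood and GLS pieces at variance ratios
        (lam_b = sigma_rat^2/sigma_1^2, lam_e = sigma_2^2/sigma_1^2)."""
        lam_b, lam_e = np.exp(theta)
        rel = np.where(ear_idx == 0, 1.0, lam_e)
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        logdet = 0.0
        blocks = []
        for idx in rat_blocks:
            d = rel[idx]
            Xi, yi = X[idx], y[idx]
            dinv = 1.0 / d
            u = dinv  # D^-1 1
            s = u.sum()
            denom = 1.0 + lam_b * s
            # W^-1 = D^-1 - lam_b/(1+lam_b*s) * u u^T  (Sherman-Morrison)
            WinvX = Xi * dinv[:, None] - (lam_b / denom) * np.outer(u, u @ Xi)
            Winvy = yi * dinv - (lam_b / denom) * u * (u @ yi)
            xtwx += Xi.T @ WinvX
            xtwy += Xi.T @ Winvy
            logdet += np.sum(np.log(d)) + np.log(denom)
            blocks.append((idx, Winvy, WinvX))
        beta = np.linalg.solve(xtwx, xtwy)
        q = 0.0
        for idx, Winvy, WinvX in blocks:
            ri = y[idx] - X[idx] @ beta
            q += ri @ (Winvy - WinvX @ beta)
        sigma2 = q / (n - p)
        sign, logdet_xtwx = np.linalg.slogdet(xtwx)
        m2reml = (n - p) * np.log(sigma2) + logdet + logdet_xtwx
        return m2reml, beta, xtwx, sigma2, (lam_b, lam_e)

    res = optimize.minimize(
        lambda th: profile(th)[0], x0=np.array([0.0, 0.0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    m2reml, beta, xtwx, sigma2, (lam_b, lam_e) = profile(res.x)
    cov_beta = sigma2 * np.linalg.inv(xtwx)

    # treatment F test
    q_num = len(groups) - 1
    L = np.zeros((q_num, p))
    for j in range(q_num):
        L[j, 1 + j] = 1.0
    lb = L @ beta
    f_stat = float(lb @ np.linalg.solve(L @ cov_beta @ L.T, lb) / q_num)
    df_den = n_rats - len(groups)
    p_val = float(sps.f.sf(f_stat, q_num, df_den))

    # LS-means: average over ear levels
    ls_rows, pair_rows = [], []
    def lsvec(group):
        v = np.zeros(p)
        v[0] = 1.0
        gi = groups.index(group)
        if gi > 0:
            v[gi] = 1.0
        for j in range(len(ears) - 1):
            v[len(groups) + j] = 1.0 / len(ears)
        return v

    for g in groups:
        v = lsvec(g)
        ls_rows.append({"group": g, "lsmean": float(v @ beta),
                        "se": float(np.sqrt(v @ cov_beta @ v))})
    for g1, g2 in combinations(groups, 2):
        d = lsvec(g1) - lsvec(g2)
        est = float(d @ beta)
        se = float(np.sqrt(d @ cov_beta @ d))
        t = est / se
        pw = float(2 * sps.t.sf(abs(t), df_den))
        pair_rows.append({"group1": g1, "group2": g2, "estimate": est,
                          "se": se, "t": t, "p": pw})

    sigma2_ear = {ears[0]: float(sigma2), }
    if len(ears) > 1:
        sigma2_ear[ears[1]] = float(sigma2 * lam_e)
    return MixedAnovaResult(
        treatment_F=f_stat, df_num=q_num, df_den=df_den, p=p_val,
        lsmeans=pd.DataFrame(ls_rows), pairwise=pd.DataFrame(pair_rows),
        sigma2_rat=float(sigma2 * lam_b), sigma2_ear=sigma2_ear,
        beta=beta, reml=float(m2reml),
    )


def ho1_percent_change_table(records: pd.DataFrame) -> pd.DataFrame:
    """Attach per-image percent change to a long-format intensity table."""
    out = records.copy()
    out["value"] = percent_change(out["roi_mean"].to_numpy(),
                                  out["background_mean"].to_numpy())
    return out
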