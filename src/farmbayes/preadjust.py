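"""Test-day record pre-adjustment and repeated-record residual weights.

Raw monthly test-day (TD) milk records are corrected for management fixed
effects — cattle development center (CDC), season, their interaction, parity,
and third-order Legendre lactation curves nested in parity and in CDC — then
averaged per cow to give a single adjusted phenotype.  Farm effects are
predicted in a second stage by ridge shrinkage of the fixed-model residuals.
The sum of a cow's estimated CDC effect and predicted farm effect scores its
production environment; cows are ranked and split into low/medium/high
terciles.  Because the phenotype is an average of r_i records, its residual
variance is not constant: each cow receives the classical repeated-records
weight

    w_i = r_i (1 - h2) / (1 + (r_i - 1) t - r_i h2),

with h2 the single-record heritability and t the repeatability (defaults
0.19 and 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentConfig",
    "AdjustmentFit",
    "legendre_basis",
    "fit_testday_adjustment",
    "adjust_and_average",
    "classify_environment",
    "garrick_weight",
    "REQUIRED_TD_COLUMNS",
]

REQUIRED_TD_COLUMNS = ("cow_id", "farm_id", "cdc_id", "season", "parity", "dim", "yield")


# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class AdjustmentConfig:
    """Model terms for the TD fixed-effect correction (all reference-coded)."""

    legendre_order: int = 3
    dim_range: tuple[float, float] = (5.0, 305.0)
    include_cdc: bool = True
    include_season: bool = True
    include_cdc_season: bool = True
    include_parity: bool = True
    include_parity_curves: bool = True
    include_cdc_curves: bool = True
    farm_variance_ratio: float = 3.0  # farm-to-residual variance ratio for shrinkage

    def __post_init__(self):
        if self.legendre_order < 0:
            raise ValueError("legendre_order must be >= 0")
        lo, hi = self.dim_range
        if not lo < hi:
            raise ValueError("dim_range must satisfy lo < hi")
        if self.farm_variance_ratio <= 0:
            raise ValueError("farm_variance_ratio must be positive")


@dataclass
class AdjustmentFit:
    """Fitted fixed effects plus shrunken farm-effect predictions."""

    config: AdjustmentConfig
    coef: pd.Series                      # indexed by design-column name
    levels: dict                         # factor -> ordered list of levels
    farm_effects: pd.Series              # indexed by farm_id
    residual_variance: float = float("nan")

    @classmethod
    def null(cls, config: AdjustmentConfig | None = None) -> "AdjustmentFit":
        """A zero fit: adjustment subtracts nothing (identity correction)."""
        cfg = config if config is not None else AdjustmentConfig(
            include_cdc=False, include_season=False, include_cdc_season=False,
            include_parity=False, include_parity_curves=False, include_cdc_curves=False,
        )
        return cls(
            config=cfg,
            coef=pd.Series({"intercept": 0.0}),
            levels={},
            farm_effects=pd.Series(dtype=float),
        )

    def cdc_effect(self, cdc_id) -> float:
        """Estimated CDC fixed effect (0 for the reference level)."""
        if "cdc" in self.levels and cdc_id not in self.levels["cdc"]:
            raise KeyError(f"CDC level {cdc_id!r} was not in the fitted data")
        return float(self.coef.get(f"cdc[{cdc_id}]", 0.0))


# ---------------------------------------------------------------------- #
def legendre_basis(dim_values, order: int, dim_range=(5.0, 305.0)) -> np.ndarray:
    """Legendre polynomials P_0..P_order of days-in-milk mapped to [-1, 1]."""
    dim_values = np.asarray(dim_values, dtype=float)
    lo, hi = dim_range
    if not lo < hi:
        raise ValueError("dim_range must satisfy lo < hi")
    bad = (dim_values < lo) | (dim_values > hi)
    if bad.any():
        offenders = np.unique(dim_values[bad])[:10]
        raise ValueError(f"days-in-milk outside [{lo}, {hi}]: {offenders.tolist()}")
    x = 2.0 * (dim_values - lo) / (hi - lo) - 1.0
    # legvander gives unnormalized P_k(x) columns, exactly what we want
    return np.polynomial.legendre.legvander(x, order)


def garrick_weight(r_i, h2: float, t: float):
    """Residual weight for a phenotype that averages r_i repeated records.

    w = r (1 - h2) / (1 + (r - 1) t - r h2); w(1) = 1 exactly and w increases
    toward (1 - h2)/(t - h2) as r grows.  Vectorized over r_i.
    """
    r = np.asarray(r_i)
    scalar = r.ndim == 0
    r = np.atleast_1d(r).astype(float)
    if (r < 1).any():
        raise ValueError("record counts r_i must be >= 1")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be inside (0, 1)")
    if not h2 <= t < 1.0:
        raise ValueError("repeatability t must satisfy h2 <= t < 1")
    denom = 1.0 + (r - 1.0) * t - r * h2
    if (denom <= 0).any():
        j = int(np.argmax(denom <= 0))
        raise ValueError(f"nonpositive weight denominator for (r={r[j]}, h2={h2}, t={t})")
    w = r * (1.0 - h2) / denom
    return float(w[0]) if scalar else w


# ---------------------------------------------------------------------- #
# design construction (shared by fit and adjust so columns always agree)
# ---------------------------------------------------------------------- #
def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_TD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"TD records missing columns: {missing}")
    if (records["yield"] < 0).any():
        raise ValueError("negative milk yields in TD records")
    if (records["parity"] < 1).any():
        raise ValueError("parity must be >= 1")
    return records


def _design(records: pd.DataFrame, cfg: AdjustmentConfig, levels: dict | None):
    """Design matrix with reference-level coding; returns (X, names, levels)."""
    fitting = levels is None
    lv: dict = {} if fitting else levels

    def factor_levels(name, col):
        obs = pd.unique(records[col])
        if fitting:
            lv[name] = sorted(obs.tolist())
        else:
            unseen = set(obs) - set(lv.get(name, []))
            if unseen:
                raise KeyError(f"unseen {name} level(s) {sorted(unseen)!r} in records")
        return lv[name]

    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]

    P = legendre_basis(records["dim"].to_numpy(), cfg.legendre_order, cfg.dim_range)

    if cfg.include_cdc or cfg.include_cdc_season or cfg.include_cdc_curves:
        cdc_levels = factor_levels("cdc", "cdc_id")
    if cfg.include_season or cfg.include_cdc_season:
        season_levels = factor_levels("season", "season")
    if cfg.include_parity or cfg.include_parity_curves:
        parity_levels = factor_levels("parity", "parity")

    if cfg.include_cdc:
        for c in cdc_levels[1:]:
            cols.append((records["cdc_id"] == c).to_numpy(float))
            names.append(f"cdc[{c}]")
    if cfg.include_season:
        for s in season_levels[1:]:
            cols.append((records["season"] == s).to_numpy(float))
            names.append(f"season[{s}]")
    if cfg.include_cdc_season:
        for c in cdc_levels[1:]:
            for s in season_levels[1:]:
                cols.append(
                    ((records["cdc_id"] == c) & (records["season"] == s)).to_numpy(float)
                )
                names.append(f"cdc[{c}]:season[{s}]")
    if cfg.include_parity:
        for p in parity_levels[1:]:
            cols.append((records["parity"] == p).to_numpy(float))
            names.append(f"parity[{p}]")
    if cfg.include_parity_curves:
        # every parity gets its own curve; the common curve is their span
        for p in parity_levels:
            ind = (records["parity"] == p).to_numpy(float)
            for k in range(1, cfg.legendre_order + 1):
                cols.append(ind * P[:, k])
                names.append(f"parity[{p}]:P{k}")
    if cfg.include_cdc_curves:
        # nested curves for non-reference CDC (reference curve lives in the
        # parity-nested block) to keep the design full rank
        for c in cdc_levels[1:]:
            ind = (records["cdc_id"] == c).to_numpy(float)
            for k in range(1, cfg.legendre_order + 1):
                cols.append(ind * P[:, k])
                names.append(f"cdc[{c}]:P{k}")

    X = np.column_stack(cols)
    return X, names, lv


# ---------------------------------------------------------------------- #
def fit_testday_adjustment(
    records: pd.DataFrame, config: AdjustmentConfig | None = None
) -> AdjustmentFit:
    """Fit the TD fixed-effect model, then shrink farm effects from residuals.

    Stage 1 solves the reference-coded fixed model by least squares; a design
    that is rank-deficient beyond the reference constraints raises with the
    names of the confounded columns.  Stage 2 predicts farm effects by ridge
    shrinkage of per-farm residual means with lambda = 1 / farm_variance_ratio
    (the assumed residual-to-farm variance ratio).
    """
    cfg = config if config is not None else AdjustmentConfig()
    records = _check_records(records)
    X, names, levels = _design(records, cfg, None)
    y = records["yield"].to_numpy(float)

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify offending columns through pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; confounded terms: {bad}")

    resid = y - X @ coef
    dof = max(len(y) - rank, 1)
    sigma_e2 = float(resid @ resid / dof)

    lam = 1.0 / cfg.farm_variance_ratio
    farm_ids = records["farm_id"].to_numpy()
    df = pd.DataFrame({"farm": farm_ids, "resid": resid})
    grp = df.groupby("farm")["resid"].agg(["sum", "count"])
    farm_effects = grp["sum"] / (grp["count"] + lam)
    farm_effects.index.name = "farm_id"

    return AdjustmentFit(
        config=cfg,
        coef=pd.Series(coef, index=names),
        levels=levels,
        farm_effects=farm_effects,
        residual_variance=sigma_e2,
    )


def adjust_and_average(records: pd.DataFrame, fit: AdjustmentFit) -> pd.DataFrame:
    """Subtract each record's fixed-effect prediction and average per cow.

    The intercept is kept (adjusted records stay on the yield scale); farm
    effects are deliberately NOT subtracted — they are modeled downstream as
    random effects.  Returns one row per cow: cow_id, farm_id, cdc_id,
    adjusted_mean, n_records.
    """
    records = _check_records(records)
    X, names, _ = _design(records, fit.config, fit.levels)
    coef = fit.coef.reindex(names)
    if coef.isna().any():
        missing = coef.index[coef.isna()].tolist()
        raise KeyError(f"fit lacks coefficients for design columns: {missing}")
    pred = X @ coef.to_numpy()
    intercept = float(fit.coef.get("intercept", 0.0))
    adjusted = records["yield"].to_numpy(float) - pred + intercept

    out = (
        records.assign(_adj=adjusted)
        .groupby("cow_id", sort=True)
        .agg(
            farm_id=("farm_id", "first"),
            cdc_id=("cdc_id", "first"),
            adjusted_mean=("_adj", "mean"),
            n_records=("_adj", "size"),
        )
        .reset_index()
    )
    if not np.isfinite(out["adjusted_mean"]).all():
        raise ValueError("non-finite adjusted means")
    return out


def classify_environment(fit: AdjustmentFit, cows: pd.DataFrame) -> pd.Series:
    """Tercile production-environment class per cow (low/medium/high).

    The environment score of a cow is its estimated CDC fixed effect plus its
    predicted farm effect.  Cows are ranked by (score, cow_id) — the stable
    tie rule — and split so class sizes differ by at most one.
    """
    for col in ("cow_id", "farm_id", "cdc_id"):
        if col not in cows.columns:
            raise ValueError(f"cows table missing column {col!r}")
    scores = []
    for _, row in cows.iterrows():
        cdc_eff = fit.cdc_effect(row["cdc_id"])
        if row["farm_id"] not in fit.farm_effects.index:
            raise KeyError(f"no farm prediction for farm {row['farm_id']!r}")
        scores.append(cdc_eff + float(fit.farm_effects.loc[row["farm_id"]]))
    df = cows[["cow_id"]].copy()
    df["score"] = scores
    order = df.sort_values(["score", "cow_id"], kind="stable").index
    n = len(df)
    labels = np.empty(n, dtype=object)
    for rank, idx in enumerate(order):
        labels[df.index.get_loc(idx)] = ("low", "medium", "high")[rank * 3 // n]
    return pd.Series(labels, index=cows.index, name="env_class")
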