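"""Smooth models of motility vs fork length, sex and island.

The candidate set comprises nine additive models of edge density (ED):
a penalized cubic regression-spline smooth of fork length, optionally
sex-specific ("by-sex"), plus optional sex and island factor terms, and
the two factor-only models.  Smooths use a k = 5 B-spline basis with a
second-difference (P-spline) penalty; the smoothing parameter is chosen
by generalized cross-validation (GCV) per model, and model AIC uses the
effective degrees of freedom (trace of the hat matrix), so a smooth
shrunk toward a simple trend is charged accordingly.

Model comparison uses AIC, ΔAIC and Akaike weights
w_i = exp(-Δ_i/2)/Σ_j exp(-Δ_j/2); the default selection rule picks,
among models within ΔAIC < 2 of the best, the one with the highest
deviance explained (ties broken by lower AIC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from scipy.interpolate import BSpline

from .stats import akaike_weights

__all__ = [
    "CANDIDATE_SPECS",
    "REFERENCE_EDGE_DENSITY_AIC",
    "ModelFit",
    "fit_candidates",
    "model_selection_table",
    "select_model",
    "smooth_summary",
    "cohort_ttest_fl_by_sex",
]

SMOOTH_K = 5  # B-spline basis functions per smooth
SPLINE_DEGREE = 3
LAMBDA_GRID = np.logspace(-3.0, 5.0, 25)


@dataclass(frozen=True)
class CandidateSpec:
    model_id: str
    smooth: str  # "none" | "shared" | "by_sex"
    sex_term: bool
    island_term: bool


CANDIDATE_SPECS: tuple[CandidateSpec, ...] = (
    CandidateSpec("ED ~ s(FL) + Island", "shared", False, True),
    CandidateSpec("ED ~ s(FL)", "shared", False, False),
    CandidateSpec("ED ~ s(FL, by=Sex) + Sex + Island", "by_sex", True, True),
    CandidateSpec("ED ~ s(FL, by=Sex) + Island", "by_sex", False, True),
    CandidateSpec("ED ~ s(FL) + Sex + Island", "shared", True, True),
    CandidateSpec("ED ~ s(FL, by=Sex) + Sex", "by_sex", True, False),
    CandidateSpec("ED ~ s(FL) + Sex", "shared", True, False),
    CandidateSpec("ED ~ Sex", "none", True, False),
    CandidateSpec("ED ~ Island", "none", False, True),
)

#: Reference AIC column for the nine-model edge-density candidate set,
#: used in docs/tests to exercise the model-selection arithmetic.
REFERENCE_EDGE_DENSITY_AIC: dict[str, float] = {
    "ED ~ s(FL) + Island": -80.99,
    "ED ~ s(FL)": -80.86,
    "ED ~ s(FL, by=Sex) + Sex + Island": -80.17,
    "ED ~ s(FL, by=Sex) + Island": -79.73,
    "ED ~ s(FL) + Sex + Island": -79.73,
    "ED ~ s(FL, by=Sex) + Sex": -79.03,
    "ED ~ s(FL) + Sex": -78.96,
    "ED ~ Sex": -67.83,
    "ED ~ Island": -67.76,
}


# ---------------------------------------------------------------- basis


def _spline_knots(x: np.ndarray, k: int = SMOOTH_K, degree: int = SPLINE_DEGREE):
    """Knot vector giving ``k`` basis functions over the range of x."""
    n_internal = k - degree - 1
    lo, hi = float(x.min()), float(x.max())
    if n_internal > 0:
        qs = np.quantile(x, np.linspace(0, 1, n_internal + 2)[1:-1])
    else:
        qs = np.array([])
    return np.concatenate([[lo] * (degree + 1), qs, [hi] * (degree + 1)])


def _full_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, knots, SPLINE_DEGREE, extrapolate=False).toarray()


@dataclass
class _SmoothBlock:
    """One centred, penalized smooth term (possibly masked to one sex)."""

    label: str  # "all" or a sex level
    Z: np.ndarray  # k x (k-1) centering reparameterization
    S: np.ndarray  # (k-1) x (k-1) penalty in the Z parameterization
    cols: slice  # columns in the assembled design matrix


def _make_block(B: np.ndarray, mask: np.ndarray | None, label: str):
    """Centered design and penalty for one smooth; returns (X, block)."""
    k = B.shape[1]
    Bm = B if mask is None else B * mask[:, None]
    c = Bm.sum(axis=0)
    nrm = np.linalg.norm(c)
    if nrm == 0:
        c = np.ones(k)
        nrm = np.sqrt(k)
    # orthonormal null-space basis of the sum-to-zero constraint
    _, _, vt = np.linalg.svd(c[None, :] / nrm)
    Z = vt[1:].T  # k x (k-1)
    D = np.diff(np.eye(k), n=2, axis=0)
    S = Z.T @ (D.T @ D) @ Z
    return Bm @ Z, Z, S


class _PenalizedFit:
    """Gaussian additive fit with ridge-type smooth penalties, GCV-tuned."""

    def __init__(self, y, X, blocks, lam_grid=LAMBDA_GRID):
        n, p = X.shape
        XtX = X.T @ X
        Xty = X.T @ y
        best = None
        grid = [0.0] if not blocks else list(lam_grid)
        for lam in grid:
            P = np.zeros((p, p))
            for b in blocks:
                P[b.cols, b.cols] += lam * b.S
            A = XtX + P
            try:
                beta = np.linalg.solve(A, Xty)
                Ainv = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                continue
            edf = float(np.trace(Ainv @ XtX))
            resid = y - X @ beta
            rss = float(resid @ resid)
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            if best is None or gcv < best["gcv"]:
                best = {
                    "lam": lam, "beta": beta, "edf": edf, "rss": rss,
                    "gcv": gcv, "Ainv": Ainv,
                }
        if best is None:
            raise np.linalg.LinAlgError("singular design in every candidate fit")
        self.n = n
        self.lam = best["lam"]
        self.beta = best["beta"]
        self.edf = best["edf"]
        self.rss = best["rss"]
        self.scale = best["rss"] / max(n - best["edf"], 1e-8)
        self.cov = self.scale * best["Ainv"]  # Bayesian posterior covariance
        self.XtX = XtX
        tss = float(((y - y.mean()) ** 2).sum())
        tiny = 1e-12 * max(1.0, float((y**2).sum()))
        self.deviance_explained = 1.0 - self.rss / tss if tss > tiny else 0.0
        # Gaussian AIC with effective df (+1 for the scale parameter)
        self.aic = (
            n * np.log(2 * np.pi * self.rss / n) + n + 2.0 * (self.edf + 1.0)
        )


@dataclass
class ModelFit:
    spec: CandidateSpec
    fit: _PenalizedFit
    knots: np.ndarray
    blocks: list[_SmoothBlock]
    sex_levels: tuple[str, ...]
    island_levels: tuple[str, ...]
    data_index: tuple

    @property
    def aic(self) -> float:
        return float(self.fit.aic)

    @property
    def edf(self) -> float:
        return float(self.fit.edf)

    @property
    def deviance_explained_pct(self) -> float:
        return float(self.fit.deviance_explained * 100.0)

    def _design(self, fl: np.ndarray, sex: np.ndarray, island: np.ndarray):
        n = len(fl)
        cols = [np.ones((n, 1))]
        if self.spec.sex_term:
            for lev in self.sex_levels[1:]:
                cols.append((sex == lev).astype(float)[:, None])
        if self.spec.island_term:
            for lev in self.island_levels[1:]:
                cols.append((island == lev).astype(float)[:, None])
        if self.spec.smooth != "none":
            B = _full_basis(fl, self.knots)
            for b in self.blocks:
                mask = None if b.label == "all" else (sex == b.label).astype(float)
                Bm = B if mask is None else B * mask[:, None]
                cols.append(Bm @ b.Z)
        return np.hstack(cols)

    def predict(
        self, fl, sex: str = "", island: str = ""
    ) -> tuple[np.ndarray, np.ndarray]:
        """Fitted mean and standard error at fork lengths ``fl``."""
        fl = np.asarray(fl, float)
        sex_arr = np.full(len(fl), sex, dtype=object)
        isl_arr = np.full(len(fl), island, dtype=object)
        X = self._design(fl, sex_arr, isl_arr)
        mean = X @ self.fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, self.fit.cov, X))
        return mean, se


def _assemble(spec, fl, sex, island, knots, sex_levels, island_levels):
    n = len(fl)
    cols = [np.ones((n, 1))]
    if spec.sex_term:
        for lev in sex_levels[1:]:
            cols.append((sex == lev).astype(float)[:, None])
    if spec.island_term:
        for lev in island_levels[1:]:
            cols.append((island == lev).astype(float)[:, None])
    blocks: list[_SmoothBlock] = []
    if spec.smooth != "none":
        B = _full_basis(fl, knots)
        labels = ["all"] if spec.smooth == "shared" else list(sex_levels)
        for label in labels:
            mask = None if label == "all" else (sex == label).astype(float)
            Xs, Z, S = _make_block(B, mask, label)
            start = sum(c.shape[1] for c in cols)
            blocks.append(
                _SmoothBlock(label, Z, S, slice(start, start + Xs.shape[1]))
            )
            cols.append(Xs)
    return np.hstack(cols), blocks


def fit_candidates(
    motility: pd.DataFrame,
    response: str = "edge_density",
    specs=CANDIDATE_SPECS,
    fl_col: str = "fl_first_detection_cm",
) -> dict[str, ModelFit]:
    """Fit every candidate model to one set of motility records."""
    required = {response, fl_col, "sex", "island"}
    missing = required - set(motility.columns)
    if missing:
        raise ValueError(f"motility records missing columns: {sorted(missing)}")
    df = motility.dropna(subset=list(required)).reset_index(drop=True)
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete motility records, have {len(df)}")
    fl = df[fl_col].to_numpy(float)
    sex = df["sex"].astype(str).to_numpy()
    island = df["island"].astype(str).to_numpy()
    y = df[response].to_numpy(float)
    sex_levels = tuple(sorted(set(sex)))
    island_levels = tuple(sorted(set(island)))
    knots = _spline_knots(fl)
    specs = list(specs)
    if len(sex_levels) < 2:
        dropped = [s.model_id for s in specs if s.sex_term or s.smooth == "by_sex"]
        if dropped:
            warnings.warn(
                f"single sex present; dropping sex models: {dropped}", stacklevel=2
            )
        specs = [s for s in specs if not (s.sex_term or s.smooth == "by_sex")]
    fits = {}
    index = tuple(df.index)
    for spec in specs:
        X, blocks = _assemble(
            spec, fl, sex, island, knots, sex_levels, island_levels
        )
        fit = _PenalizedFit(y, X, blocks)
        fits[spec.model_id] = ModelFit(
            spec, fit, knots, blocks, sex_levels, island_levels, index
        )
    return fits


def model_selection_table(fits_or_aic) -> pd.DataFrame:
    """AIC / ΔAIC / Akaike weight / deviance-explained table.

    Accepts either the dict of fitted models or a plain
    ``{model_id: aic}`` mapping (deviance column omitted in that case).
    """
    items = list(fits_or_aic.items())
    if not items:
        raise ValueError("no models to compare")
    have_fits = isinstance(items[0][1], ModelFit)
    if have_fits:
        indexes = {f.data_index for _, f in items}
        if len(indexes) > 1:
            raise ValueError("candidate models were fitted on different records")
        rows = pd.DataFrame(
            {
                "model_id": [k for k, _ in items],
                "aic": [f.aic for _, f in items],
                "edf": [f.edf for _, f in items],
                "deviance_explained_pct": [
                    f.deviance_explained_pct for _, f in items
                ],
            }
        )
    else:
        rows = pd.DataFrame(
            {"model_id": [k for k, _ in items], "aic": [float(v) for _, v in items]}
        )
    delta, w = akaike_weights(rows["aic"].to_numpy())
    rows["delta_aic"] = delta
    rows["akaike_weight"] = w
    order = ["model_id", "aic", "delta_aic", "akaike_weight"]
    for extra in ("edf", "deviance_explained_pct"):
        if extra in rows:
            order.append(extra)
    return (
        rows[order]
        .sort_values(["aic", "model_id"], kind="mergesort")
        .reset_index(drop=True)
    )


def select_model(table: pd.DataFrame, rule: str = "deviance_within_2") -> dict:
    """Pick a model from the selection table.

    ``deviance_within_2`` (default): among rows with ΔAIC < 2, highest
    deviance explained, ties to lower AIC.  ``aic``: lowest AIC.
    """
    if table.empty:
        raise ValueError("empty model-selection table")
    if rule == "aic" or "deviance_explained_pct" not in table.columns:
        best = table.sort_values(["aic", "model_id"], kind="mergesort").iloc[0]
        rationale = "lowest AIC"
    elif rule == "deviance_within_2":
        pool = table[table["delta_aic"] < 2.0]
        best = pool.sort_values(
            ["deviance_explained_pct", "aic"],
            ascending=[False, True],
            kind="mergesort",
        ).iloc[0]
        rationale = (
            f"highest deviance explained ({best['deviance_explained_pct']:.2f}%) "
            f"among {len(pool)} models with dAIC < 2"
        )
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return {"model_id": best["model_id"], "rule": rule, "rationale": rationale,
            "delta_aic": float(best["delta_aic"])}


def smooth_summary(
    fit: ModelFit,
    motility: pd.DataFrame,
    sex_level: str | None = None,
    fl_col: str = "fl_first_detection_cm",
    grid_size: int = 201,
) -> dict:
    """Shape, Wald F-test and (if unimodal) peak location of a smooth.

    The smooth is "unimodal" when the fitted curve has exactly one
    interior maximum exceeding both endpoints by more than one standard
    error; "linear" when it has no interior extremum; "other" otherwise.
    Monotonicity is judged with a small tolerance (1% of the fitted
    range) to ignore numerically flat stretches.
    """
    key = sex_level if fit.spec.smooth == "by_sex" else "all"
    block = next((b for b in fit.blocks if b.label == key), None)
    if block is None:
        raise ValueError(f"model {fit.spec.model_id!r} has no smooth for {key!r}")
    beta_s = fit.fit.beta[block.cols]
    cov_s = fit.fit.cov[block.cols, block.cols]
    r = len(beta_s)
    try:
        fstat = float(beta_s @ np.linalg.solve(cov_s, beta_s)) / r
    except np.linalg.LinAlgError:
        fstat = np.nan
    df_resid = max(fit.fit.n - fit.fit.edf, 1.0)
    pval = float(sp_stats.f.sf(fstat, r, df_resid)) if np.isfinite(fstat) else np.nan

    df_sub = motility
    if sex_level is not None and "sex" in motility.columns:
        df_sub = motility[motility["sex"].astype(str) == sex_level]
    fl = df_sub[fl_col].to_numpy(float)
    grid = np.linspace(fl.min(), fl.max(), grid_size)
    mean, se = fit.predict(
        grid, sex=sex_level or fit.sex_levels[0], island=fit.island_levels[0]
    )
    interior_max = [
        i
        for i in range(1, grid_size - 1)
        if mean[i] > mean[i - 1] and mean[i] >= mean[i + 1]
    ]
    interior_min = [
        i
        for i in range(1, grid_size - 1)
        if mean[i] < mean[i - 1] and mean[i] <= mean[i + 1]
    ]
    shape = "other"
    peak = None
    if not interior_max and not interior_min:
        shape = "linear"
    elif len(interior_max) == 1 and not interior_min:
        i = interior_max[0]
        if mean[i] > mean[0] + se[i] and mean[i] > mean[-1] + se[i]:
            shape = "unimodal"
            peak = float(grid[i])
    tol = 0.01 * (mean.max() - mean.min())
    am = int(np.argmax(mean))
    interior_peak = float(grid[am]) if 0 < am < grid_size - 1 else None
    return {
        "term": f"s(FL){'' if key == 'all' else ':' + key}",
        "sex_level": sex_level,
        "f_stat": fstat,
        "p_value": pval,
        "effective_df": r,
        "shape_class": shape,
        "peak_fl_cm": peak,
        "interior_peak_fl_cm": interior_peak,
        "trend_increasing": bool(mean[-1] > mean[0]),
        "monotone_increasing": bool(np.all(np.diff(mean) >= -tol)),
    }


def cohort_ttest_fl_by_sex(
    staged: pd.DataFrame, fl_col: str = "fl_first_detection_cm"
) -> dict:
    """Pooled-variance two-sample t-test of fork length between sexes."""
    sexes = staged["sex"].astype(str).str.upper().str[:1]
    a = staged.loc[sexes == "F", fl_col].dropna().to_numpy(float)
    b = staged.loc[sexes == "M", fl_col].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs >= 2 sharks of each sex")
    t, p = sp_stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "df": len(a) + len(b) - 2, "p": float(p),
            "n_female": len(a), "n_male": len(b)}
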