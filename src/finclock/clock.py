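"""Elastic-net epigenetic clock on ln(age).

Training follows the de novo clock recipe: an 80/20 train/test partition, a
Pearson prefilter keeping the sites most correlated with age, a natural-log
transform of otolith-derived age, and a random-subset search in which small
site subsets are repeatedly drawn (with replacement) and an elastic net is
cross-validated over both the mixing parameter alpha and the penalty lambda;
the subset minimising cross-validated mean absolute error (in years, after
back-transforming) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

from ._utils import logger

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 2))


@dataclass
class PartitionSpec:
    """Disjoint train/test fish ids covering the whole cohort."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def partition_train_test(
    fish_ids,
    integer_ages=None,
    train_frac: float = 0.8,
    stratify_by_age_bin: bool = True,
    seed: int | None = None,
) -> PartitionSpec:
    """Random train/test split; |train| = round(train_frac * n).

    With stratification, integer-age bins contribute proportionally to the
    training set (largest-remainder allocation), so rare ages appear on both
    sides where possible.
    """
    fish_ids = list(fish_ids)
    n = len(fish_ids)
    if n < 5:
        raise ValueError("need at least 5 fish to partition")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)

    if not stratify_by_age_bin or integer_ages is None:
        perm = rng.permutation(n)
        train_idx = set(perm[:n_train].tolist())
    else:
        ages = np.asarray(integer_ages)
        if ages.shape[0] != n:
            raise ValueError("integer_ages must align with fish_ids")
        bins, codes = np.unique(ages, return_inverse=True)
        quota = np.array([(codes == b).sum() for b in range(bins.size)]) * train_frac
        base = np.floor(quota).astype(int)
        remainder = n_train - base.sum()
        frac_order = np.lexsort((np.arange(bins.size), -(quota - base)))
        for b in frac_order[:remainder]:
            base[b] += 1
        train_idx = set()
        for b in range(bins.size):
            members = np.flatnonzero(codes == b)
            take = min(base[b], members.size)
            train_idx.update(rng.choice(members, size=take, replace=False).tolist())
        # largest-remainder can be off by a few when bins saturate; top up randomly
        rest = [i for i in range(n) if i not in train_idx]
        rng.shuffle(rest)
        while len(train_idx) < n_train and rest:
            train_idx.add(rest.pop())
        while len(train_idx) > n_train:
            train_idx.pop()
    train = [fish_ids[i] for i in sorted(train_idx)]
    test = [fish_ids[i] for i in range(n) if i not in train_idx]
    return PartitionSpec(train_ids=train, test_ids=test, seed=seed)


def pearson_prefilter(x: pd.DataFrame, ages, top_k: int = 1000) -> list[str]:
    """Sites ranked by |Pearson r| between methylation and (raw) age.

    Zero-variance sites are excluded; returns up to ``top_k`` site ids,
    strongest correlation first (ties by site id).
    """
    ages = np.asarray(ages, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 training fish")
    xa = x.to_numpy(dtype=float)
    xc = xa - xa.mean(axis=0)
    ac = ages - ages.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sa = np.sqrt((ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ ac) / (sx * sa)
    ok = sx > 0
    abs_r = np.where(ok, np.abs(r), -1.0)
    order = np.lexsort((np.asarray(x.columns, dtype=str), -abs_r))
    ranked = [x.columns[i] for i in order if ok[i]]
    return ranked[:top_k]


# --------------------------------------------------------------------------
# Elastic net with (alpha, lambda) cross-validation
# --------------------------------------------------------------------------

@dataclass
class ElasticNetCVResult:
    alpha: float
    lam: float
    intercept: float  # ln-years, original predictor scale
    coef: pd.Series  # original predictor scale
    train_mean: pd.Series
    train_sd: pd.Series
    cv_mae_years: float


def _standardize(xa: np.ndarray):
    mu = xa.mean(axis=0)
    sd = xa.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (xa - mu) / sd, mu, sd


def _lambda_grid(xs: np.ndarray, yc: np.ndarray, alpha: float, n_lambda: int) -> np.ndarray:
    n = xs.shape[0]
    lam_max = np.abs(xs.T @ yc).max() / (n * max(alpha, 0.05))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_lambda)


def _ridge_path(xs: np.ndarray, yc: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """Ridge solutions for all penalties via one SVD; objective matches
    (1/2n)||y - Xb||^2 + (lam/2)||b||^2. Returns (p, L)."""
    n = xs.shape[0]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    uy = u.T @ yc
    shrink = s[:, None] / (s[:, None] ** 2 + n * lams[None, :])
    return vt.T @ (shrink * uy[:, None])


def _coef_path(xs: np.ndarray, yc: np.ndarray, alpha: float, lams: np.ndarray) -> np.ndarray:
    if alpha == 0.0:
        return _ridge_path(xs, yc, lams)
    _, coefs, _ = enet_path(xs, yc, l1_ratio=alpha, alphas=lams)
    return coefs


def fit_elastic_net_cv(
    x: pd.DataFrame,
    y_ln,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_folds: int = 10,
    n_lambda: int = 100,
    seed: int | None = None,
    objective: str = "years_mae",
) -> ElasticNetCVResult:
    """Cross-validate mixing (alpha) and penalty (lambda) jointly.

    Predictors are standardised inside each fold; the response is ln(age).
    Model selection minimises cross-validated MAE computed on back-
    transformed years (``objective="ln_mae"`` switches to the ln scale).
    Coefficients are refit on the full training data at the chosen (alpha,
    lambda) and returned on the original percent-methylation scale.
    """
    if objective not in ("years_mae", "ln_mae"):
        raise ValueError(f"unknown objective {objective!r}")
    y = np.asarray(y_ln, dtype=float)
    xa = x.to_numpy(dtype=float)
    n = xa.shape[0]
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} training fish for {n_folds}-fold CV")
    alpha_grid = [float(a) for a in alpha_grid]

    xs_full, mu_full, sd_full = _standardize(xa)
    lam_grids = {
        a: _lambda_grid(xs_full, y - y.mean(), a, n_lambda) for a in alpha_grid
    }

    def run_cv(split_seed):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=split_seed)
        folds = list(kf.split(xa))
        for tr, _ in folds:
            if np.unique(y[tr]).size < 2:
                return None
        err = {a: np.zeros(n_lambda) for a in alpha_grid}
        for tr, va in folds:
            xs, mu, sd = _standardize(xa[tr])
            ybar = y[tr].mean()
            yc = y[tr] - ybar
            xv = (xa[va] - mu) / sd
            for a in alpha_grid:
                coefs = _coef_path(xs, yc, a, lam_grids[a])
                pred = xv @ coefs + ybar  # (n_val, L)
                if objective == "years_mae":
                    e = np.abs(np.exp(pred) - np.exp(y[va])[:, None])
                else:
                    e = np.abs(pred - y[va][:, None])
                err[a] += e.sum(axis=0)
        return {a: v / n for a, v in err.items()}

    base_seed = seed if seed is not None else 0
    cv_err = run_cv(base_seed)
    if cv_err is None:
        logger.warning("degenerate CV fold (constant response); reshuffling once")
        cv_err = run_cv(base_seed + 1)
        if cv_err is None:
            raise ValueError("could not build non-degenerate CV folds")

    best = None
    for a in alpha_grid:
        errs = cv_err[a]
        j = int(np.argmin(errs))  # first minimum = largest lambda = sparsest
        if best is None or errs[j] < best[0] - 1e-15:
            best = (float(errs[j]), a, float(lam_grids[a][j]), j)
    cv_mae, a_best, lam_best, j_best = best

    coefs_std = _coef_path(xs_full, y - y.mean(), a_best, lam_grids[a_best])[:, j_best]
    coef = coefs_std / sd_full
    intercept = float(y.mean() - coef @ mu_full)
    return ElasticNetCVResult(
        alpha=a_best,
        lam=lam_best,
        intercept=intercept,
        coef=pd.Series(coef, index=x.columns),
        train_mean=pd.Series(mu_full, index=x.columns),
        train_sd=pd.Series(sd_full, index=x.columns),
        cv_mae_years=cv_mae,
    )


# --------------------------------------------------------------------------
# Clock model and subset search
# --------------------------------------------------------------------------

@dataclass
class ClockModel:
    """Fitted age predictor: exp(intercept + sum coef_s * p_s)."""

    site_ids: list[str]
    coefficients: pd.Series
    intercept: float
    alpha: float
    lam: float
    train_mean: pd.Series
    train_sd: pd.Series
    transform: str = "ln_years"
    cv_mae_years: float = float("nan")

    @classmethod
    def from_cv_result(cls, res: ElasticNetCVResult) -> "ClockModel":
        return cls(
            site_ids=list(res.coef.index),
            coefficients=res.coef,
            intercept=res.intercept,
            alpha=res.alpha,
            lam=res.lam,
            train_mean=res.train_mean,
            train_sd=res.train_sd,
            cv_mae_years=res.cv_mae_years,
        )

    @property
    def n_nonzero(self) -> int:
        return int((self.coefficients != 0).sum())

    def save(self, path) -> None:
        """Structured-text serialisation (header key-values + site table)."""
        with open(path, "w") as fh:
            fh.write("# finclock model\n")
            fh.write(f"transform\t{self.transform}\n")
            fh.write(f"intercept\t{float(self.intercept)!r}\n")
            fh.write(f"alpha\t{float(self.alpha)!r}\n")
            fh.write(f"lambda\t{float(self.lam)!r}\n")
            fh.write(f"cv_mae_years\t{float(self.cv_mae_years)!r}\n")
            fh.write("site_id\tcoefficient\ttrain_mean\ttrain_sd\n")
            for s in self.site_ids:
                fh.write(
                    f"{s}\t{float(self.coefficients[s])!r}\t{float(self.train_mean[s])!r}"
                    f"\t{float(self.train_sd[s])!r}\n"
                )

    @classmethod
    def load(cls, path) -> "ClockModel":
        header: dict[str, str] = {}
        rows = []
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        table_start = next(i for i, ln in enumerate(lines) if ln.startswith("site_id\t"))
        for ln in lines[:table_start]:
            key, val = ln.split("\t", 1)
            header[key] = val
        for ln in lines[table_start + 1:]:
            s, c, m, sd = ln.split("\t")
            rows.append((s, float(c), float(m), float(sd)))
        tab = pd.DataFrame(rows, columns=["site_id", "coefficient", "train_mean", "train_sd"])
        tab = tab.set_index("site_id")
        return cls(
            site_ids=list(tab.index),
            coefficients=tab["coefficient"],
            intercept=float(header["intercept"]),
            alpha=float(header["alpha"]),
            lam=float(header["lambda"]),
            train_mean=tab["train_mean"],
            train_sd=tab["train_sd"],
            transform=header.get("transform", "ln_years"),
            cv_mae_years=float(header.get("cv_mae_years", "nan")),
        )


def predict_age(model: ClockModel, x: pd.DataFrame) -> pd.Series:
    """Predicted ages in years (strictly positive) for a fish x site table."""
    missing = [s for s in model.site_ids if s not in x.columns]
    if missing:
        raise ValueError(f"model sites absent from input: {missing}")
    sub = x[model.site_ids].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError("input contains missing values at model sites; impute first")
    ln_pred = model.intercept + sub @ model.coefficients.to_numpy()
    return pd.Series(np.exp(ln_pred), index=x.index, name="predicted_age_years")


def subset_search(
    x: pd.DataFrame,
    y_ln,
    subset_size: int = 125,
    iterations: int = 1000,
    seed: int | None = None,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_folds: int = 10,
    n_lambda: int = 100,
    objective: str = "years_mae",
    log_every: int = 50,
) -> ClockModel:
    """Random-subset search minimising cross-validated MAE.

    Each iteration samples ``subset_size`` sites with replacement (duplicates
    collapsed, since duplicated columns are degenerate under a penalty), runs
    the (alpha, lambda) cross-validation, and keeps the best model by
    ``cv_mae_years``. One fold assignment, drawn once from ``seed``, is used
    for every iteration so subsets compete on the same splits rather than on
    lucky fold draws. The winning model is refit on the full training data by
    :func:`fit_elastic_net_cv` itself.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if subset_size < 1 or subset_size > x.shape[1] * 10:
        raise ValueError("subset_size out of range")
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))  # shared CV split for all iterations
    cols = np.asarray(x.columns)
    best: ElasticNetCVResult | None = None
    for it in range(iterations):
        chosen = np.unique(rng.choice(cols, size=subset_size, replace=True))
        res = fit_elastic_net_cv(
            x[list(chosen)], y_ln, alpha_grid=alpha_grid, n_folds=n_folds,
            n_lambda=n_lambda, seed=cv_seed,
            objective=objective,
        )
        if best is None or res.cv_mae_years < best.cv_mae_years:
            best = res
            logger.info(
                "subset search iteration %d: new best cv MAE %.4f years "
                "(alpha=%.2f, %d nonzero)",
                it + 1, res.cv_mae_years, res.alpha, int((res.coef != 0).sum()),
            )
        elif (it + 1) % log_every == 0:
            logger.info(
                "subset search iteration %d: running best cv MAE %.4f years",
                it + 1, best.cv_mae_years,
            )
    assert best is not None
    return ClockModel.from_cv_result(best)
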