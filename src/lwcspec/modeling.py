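"""Calibration/validation modeling of leaf water content.

A 70/30 split of the samples, KNN/SVR/ANN regressions on the nine assembled
feature sets, and chemometric evaluation:

* R^2: squared Pearson correlation between measured and predicted values;
* RMSE = sqrt(mean squared error), in % LWC;
* RPD = SD / SEP, where SD is the (bias-corrected) standard deviation of
  the measured validation values and SEP the bias-corrected standard
  deviation of the residuals.  RPD > 2.0 marks a model with good
  predictive ability, 1.4-2.0 a general one, < 1.4 a poor one.

The `LeafWaterModel` / `LeafWaterResults` pair wraps the whole pipeline:
preprocessing, fractional-derivative computation, calibration-only band
optimization, feature assembly and the 9 x 3 model grid.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from . import bandopt
from .bandopt import BandCombo, FeatureComponents, FEATURE_KINDS, assemble_features
from .fod import fod_stack, DEFAULT_ORDERS
from .spectra import (
    SpectraSet,
    TraitVector,
    SpectraError,
    align,
    morph_smooth,
    read_spectra,
    resample_1nm,
    trim_default_windows,
)

__all__ = [
    "SplitSpec",
    "ModelConfig",
    "EvaluationReport",
    "DEFAULT_CONFIGS",
    "split_dataset",
    "evaluate",
    "rpd_class",
    "fit_predict",
    "run_model_grid",
    "LeafWaterModel",
    "LeafWaterResults",
]


@dataclass(frozen=True)
class SplitSpec:
    """Calibration/validation partition: ceil(fraction * n) calibration ids."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train fraction must be in (0, 1), got {self.train_fraction}")


def split_dataset(ids, spec: SplitSpec) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Deterministic disjoint, exhaustive split of sample ids."""
    ids = [str(s) for s in ids]
    n = len(ids)
    if n < 10:
        raise ValueError(f"need >= 10 samples to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = math.ceil(spec.train_fraction * n)
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    val = tuple(ids[i] for i in sorted(perm[n_train:]))
    return train, val


def rpd_class(rpd: float) -> str:
    if rpd > 2.0:
        return "better"
    if rpd >= 1.4:
        return "general"
    return "poor"


def evaluate(y, y_pred) -> tuple[float, float, float]:
    """(R^2, RMSE, RPD) of predictions against observations.

    R^2 is the squared correlation (0 when the predictions are constant),
    RMSE uses the population mean square, SEP is the bias-corrected
    standard deviation of the residuals and RPD = SD(y)/SEP (infinite for
    a perfect fit).
    """
    y = np.asarray(y, float)
    y_pred = np.asarray(y_pred, float)
    if y.shape != y_pred.shape or y.ndim != 1:
        raise ValueError("y and y_pred must be 1-D and aligned")
    if y.size < 3:
        raise ValueError(f"need >= 3 pairs, got {y.size}")
    if np.ptp(y) == 0.0:
        raise ValueError("observed values are constant; metrics undefined")
    resid = y - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.ptp(y_pred) == 0.0:
        r2 = 0.0
    else:
        r2 = float(bandopt.pearson_r(y, y_pred) ** 2)
    sd = float(np.std(y, ddof=1))
    sep = float(np.std(resid, ddof=1))
    rpd = float("inf") if sep == 0.0 else sd / sep
    return r2, rmse, rpd


@dataclass(frozen=True)
class ModelConfig:
    """One learner and its (small) tuning grid.

    KNN averages the targets of the k nearest calibration samples in the
    standardized feature space; k is chosen by cross-validation on the
    calibration set.  SVR uses an RBF kernel by default with a C/epsilon
    grid; the ANN is a single hidden layer of 16 units with seeded
    initialization and no tuning.
    """

    method: str
    k_grid: tuple[int, ...] = (3, 5, 7, 9)
    svr_kernel: str = "rbf"
    svr_c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    svr_epsilon_grid: tuple[float, ...] = (0.01, 0.1)
    hidden_layer_sizes: tuple[int, ...] = (16,)
    max_epochs: int = 2000
    scaling: bool = True
    cv_folds: int = 5
    impute: str = "median"

    def __post_init__(self) -> None:
        if self.method not in ("KNN", "SVR", "ANN"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "KNN" and not self.k_grid:
            raise ValueError("empty k grid")
        if self.method == "SVR" and not (self.svr_c_grid and self.svr_epsilon_grid):
            raise ValueError("empty SVR grid")


DEFAULT_CONFIGS: dict[str, ModelConfig] = {
    "KNN": ModelConfig("KNN"),
    "SVR": ModelConfig("SVR"),
    "ANN": ModelConfig("ANN"),
}


@dataclass(frozen=True)
class EvaluationReport:
    """Calibration and validation metrics for one feature-set x learner cell."""

    data_type: str
    method: str
    r2_sim: float
    rmse_sim: float
    r2_pre: float
    rmse_pre: float
    rpd: float
    rpd_class: str

    def to_dict(self) -> dict:
        return asdict(self)


def _estimator(cfg: ModelConfig, n_train: int, seed: int):
    steps = [("impute", SimpleImputer(strategy=cfg.impute))]
    if cfg.scaling:
        steps.append(("scale", StandardScaler()))
    cv = KFold(n_splits=min(cfg.cv_folds, n_train))
    if cfg.method == "KNN":
        ks = [k for k in cfg.k_grid if k <= n_train]
        if not ks:
            raise ValueError(
                f"all k in {cfg.k_grid} exceed the {n_train} calibration samples"
            )
        pipe = Pipeline(steps + [("model", KNeighborsRegressor())])
        if len(ks) == 1:
            return pipe.set_params(model__n_neighbors=ks[0])
        return GridSearchCV(pipe, {"model__n_neighbors": ks}, cv=cv,
                            scoring="neg_root_mean_squared_error")
    if cfg.method == "SVR":
        pipe = Pipeline(steps + [("model", SVR(kernel=cfg.svr_kernel))])
        grid = {"model__C": list(cfg.svr_c_grid),
                "model__epsilon": list(cfg.svr_epsilon_grid)}
        if len(cfg.svr_c_grid) == 1 and len(cfg.svr_epsilon_grid) == 1:
            return pipe.set_params(model__C=cfg.svr_c_grid[0],
                                   model__epsilon=cfg.svr_epsilon_grid[0])
        return GridSearchCV(pipe, grid, cv=cv,
                            scoring="neg_root_mean_squared_error")
    # Targets are standardized for the network (fitted on calibration data
    # only); without it the default learning rate never reaches the ~78 %
    # LWC scale within the epoch budget.
    net = Pipeline(steps + [("model", MLPRegressor(
        hidden_layer_sizes=cfg.hidden_layer_sizes,
        max_iter=cfg.max_epochs,
        random_state=seed,
    ))])
    return TransformedTargetRegressor(regressor=net, transformer=StandardScaler())


def fit_predict(X_train, y_train, X_eval, cfg: ModelConfig, seed: int = 0) -> np.ndarray:
    """Fit one learner on the calibration data and predict on X_eval.

    Imputation (column median), standardization and hyperparameter tuning
    are all fitted on the calibration data only.
    """
    X_train = np.asarray(X_train, float)
    X_eval = np.asarray(X_eval, float)
    y_train = np.asarray(y_train, float)
    if np.isinf(X_train).any() or np.isinf(X_eval).any():
        raise ValueError("non-finite (infinite) feature values")
    est = _estimator(cfg, len(y_train), seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_train, y_train)
        return np.asarray(est.predict(X_eval), float)


def run_model_grid(
    features: dict[str, pd.DataFrame],
    trait: TraitVector,
    split: tuple[tuple[str, ...], tuple[str, ...]],
    configs: dict[str, ModelConfig] = DEFAULT_CONFIGS,
    seed: int = 0,
) -> list[EvaluationReport]:
    """Fit every feature-set x learner cell and evaluate both subsets.

    With the nine canonical feature sets and three learners this yields the
    27-model grid.  Any failing cell aborts with the offending cell named.
    """
    train_ids, val_ids = split
    reports = []
    for d, (kind, X) in enumerate(features.items()):
        Xtr = X.loc[list(train_ids)].to_numpy(float)
        Xva = X.loc[list(val_ids)].to_numpy(float)
        ytr = trait.subset(train_ids).values
        yva = trait.subset(val_ids).values
        for m, (name, cfg) in enumerate(configs.items()):
            try:
                pred_tr = fit_predict(Xtr, ytr, Xtr, cfg, seed=seed + 1000 * d + m)
                pred_va = fit_predict(Xtr, ytr, Xva, cfg, seed=seed + 1000 * d + m)
                r2s, rmses, _ = evaluate(ytr, pred_tr)
                r2p, rmsep, rpd = evaluate(yva, pred_va)
            except Exception as exc:
                raise RuntimeError(
                    f"model grid failed at data type {kind!r}, method {name!r}: {exc}"
                ) from exc
            reports.append(
                EvaluationReport(kind, name, r2s, rmses, r2p, rmsep, rpd, rpd_class(rpd))
            )
    return reports


def reports_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    df = pd.DataFrame([r.to_dict() for r in reports])
    return df.rename(
        columns={
            "r2_sim": "R2_sim",
            "rmse_sim": "RMSE_sim",
            "r2_pre": "R2_pre",
            "rmse_pre": "RMSE_pre",
            "rpd": "RPD",
        }
    )


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class LeafWaterModel:
    """End-to-end leaf-water-content estimation from canopy spectra.

    Parameters
    ----------
    spectra : SpectraSet
        Raw reflectance spectra (any grid; resampled to 1 nm internally).
    trait : TraitVector
        Leaf water content (%) per sample.
    preprocess : bool
        Resample to 1 nm, remove the default noisy windows and apply the
        morphological smoother before any analysis.
    derivative_order : float
        Fractional order used for the derivative-based feature sets
        (default 0.8, the order at which water-related correlations peak).
    orders : sequence of float
        Orders for the exploratory derivative scan (default 0.0-2.0 by 0.2).
    two_band_stride, three_band_stride : int
        Search strides (nm) for the 2-D and 3-D band optimization.
    three_band_range : (float, float)
        Wavelength window of the three-band search (default 400-1300 nm,
        the region where two-band combinations are significant).
    raw_window, fod_window : (float, float)
        Windows from which the "sensitive single band" feature sets are
        drawn (769-924 nm for raw reflectance, 711-875 nm for the
        derivative spectra).
    alpha : float
        Significance level of the correlation screen (default 0.01).
    """

    def __init__(
        self,
        spectra: SpectraSet,
        trait: TraitVector,
        *,
        preprocess: bool = True,
        smooth_width: int = 7,
        derivative_order: float = 0.8,
        orders=DEFAULT_ORDERS,
        two_band_stride: int = 1,
        two_band_range: tuple[float, float] | None = None,
        three_band_stride: int = 5,
        three_band_range: tuple[float, float] = (400, 1300),
        refine: bool = True,
        alpha: float = 0.01,
        raw_window: tuple[float, float] = (769, 924),
        fod_window: tuple[float, float] = (711, 875),
        split: SplitSpec | None = None,
        configs: dict[str, ModelConfig] = DEFAULT_CONFIGS,
        run_order_scan: bool = True,
    ) -> None:
        self.spectra, self.trait = align(spectra, trait)
        self.preprocess = preprocess
        self.smooth_width = smooth_width
        self.derivative_order = float(derivative_order)
        self.orders = tuple(orders)
        self.two_band_stride = two_band_stride
        self.two_band_range = two_band_range
        self.three_band_stride = three_band_stride
        self.three_band_range = three_band_range
        self.refine = refine
        self.alpha = alpha
        self.raw_window = raw_window
        self.fod_window = fod_window
        self.split_spec = split or SplitSpec()
        self.configs = dict(configs)
        self.run_order_scan = run_order_scan

    @classmethod
    def from_csv(cls, spectra_path, trait_path, **kwargs) -> "LeafWaterModel":
        s, t = read_spectra(spectra_path, trait_path)
        return cls(s, t, **kwargs)

    # -- pipeline steps ----------------------------------------------------
    def _preprocessed(self) -> SpectraSet:
        s = self.spectra
        if self.preprocess:
            s = trim_default_windows(resample_1nm(s))
            s = morph_smooth(s, self.smooth_width)
        return s

    def _sensitive_bands(
        self, s: SpectraSet, t: TraitVector, window: tuple[float, float]
    ) -> tuple[float, ...]:
        """Bands passing the screen inside ``window``; top-5 |r| fallback."""
        tab = bandopt.corr_1d(s, t, alpha=self.alpha)
        inside = tab[(tab.wavelength >= window[0]) & (tab.wavelength <= window[1])]
        chosen = inside[inside.significant]
        if chosen.empty:
            finite = inside.dropna(subset=["r"])
            chosen = finite.loc[finite.r.abs().nlargest(5).index]
        return tuple(float(w) for w in sorted(chosen.wavelength))

    def fit(self, seed: int | None = None) -> "LeafWaterResults":
        """Run the full pipeline and return the results object.

        All band selections and hyperparameter tuning see only the
        calibration subset; validation samples enter only at evaluation.
        """
        split_spec = self.split_spec if seed is None else SplitSpec(
            self.split_spec.train_fraction, seed
        )
        s = self._preprocessed()
        t = self.trait
        stack = fod_stack(s, sorted({*self.orders, 0.0, self.derivative_order}))
        fod_s = stack[self.derivative_order]

        train_ids, val_ids = split_dataset(s.sample_ids, split_spec)
        s_tr, t_tr = s.subset(train_ids), t.subset(train_ids)
        fod_tr = fod_s.subset(train_ids)

        order_summary = (
            bandopt.order_scan(
                fod_stack(s_tr, self.orders), t_tr, alpha=self.alpha
            )
            if self.run_order_scan
            else None
        )

        comp = FeatureComponents(
            raw=s,
            fod=fod_s,
            fod_order=self.derivative_order,
            sensitive_raw=self._sensitive_bands(s_tr, t_tr, self.raw_window),
            sensitive_fod=self._sensitive_bands(fod_tr, t_tr, self.fod_window),
        )

        comp.best_2bi_raw = {}
        comp.best_2bi_fod = {}
        for form in ("DVI", "RVI", "NDVI"):
            _, comp.best_2bi_raw[form] = bandopt.corr_map_2d(
                s_tr, t_tr, form, band_range=self.two_band_range,
                stride=self.two_band_stride, alpha=self.alpha, order=0.0,
            )
            _, comp.best_2bi_fod[form] = bandopt.corr_map_2d(
                fod_tr, t_tr, form, band_range=self.two_band_range,
                stride=self.two_band_stride, alpha=self.alpha,
                order=self.derivative_order,
            )
        comp.best_3bi = {}
        for form in ("3BI-1", "3BI-2", "3BI-3", "3BI-4", "3BI-5", "3BI-6", "3BI-7"):
            comp.best_3bi[form], _ = bandopt.corr_search_3d(
                fod_tr, t_tr, form, band_range=self.three_band_range,
                stride=self.three_band_stride, refine=self.refine,
                alpha=self.alpha, order=self.derivative_order,
            )

        features = {kind: assemble_features(kind, comp) for kind in FEATURE_KINDS}
        reports = run_model_grid(
            features, t, (train_ids, val_ids), self.configs, seed=split_spec.seed
        )
        return LeafWaterResults(
            model=self,
            components=comp,
            features=features,
            reports=reports,
            train_ids=train_ids,
            val_ids=val_ids,
            selection_ids=train_ids,
            order_summary=order_summary,
            seed=split_spec.seed,
        )


@dataclass
class LeafWaterResults:
    """Fitted pipeline: band optima, feature sets and the 9 x 3 report grid."""

    model: LeafWaterModel
    components: FeatureComponents
    features: dict[str, pd.DataFrame]
    reports: list[EvaluationReport]
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    selection_ids: tuple[str, ...]
    order_summary: pd.DataFrame | None
    seed: int

    def reports_frame(self) -> pd.DataFrame:
        return reports_frame(self.reports)

    def combos_frame(self) -> pd.DataFrame:
        rows = []
        groups = (
            ("2BI", self.components.best_2bi_raw or {}),
            ("2BI-FOD", self.components.best_2bi_fod or {}),
            ("3BI", self.components.best_3bi or {}),
        )
        for group, combos in groups:
            for form, c in combos.items():
                rows.append(
                    {
                        "group": group,
                        "form": form,
                        "order": c.order,
                        "wavelengths_nm": " ".join(f"{w:g}" for w in c.wavelengths),
                        "r": c.r,
                        "n_valid": c.n_valid,
                        "significant": c.significant,
                    }
                )
        return pd.DataFrame(rows)

    @property
    def best(self) -> EvaluationReport:
        """The cell with the highest validation R^2 (RPD breaks ties)."""
        return max(self.reports, key=lambda r: (r.r2_pre, r.rpd))

    def best_by_data_type(self) -> pd.DataFrame:
        df = self.reports_frame()
        idx = df.groupby("data_type", sort=False)["R2_pre"].idxmax()
        out = df.loc[idx].reset_index(drop=True)
        return out

    def summary(self) -> str:
        df = self.reports_frame()
        combos = self.combos_frame()
        b = self.best
        lines = [
            "Leaf water content estimation - calibration summary",
            "=" * 67,
            f"samples: {len(self.train_ids)} calibration / {len(self.val_ids)} validation"
            f"  (seed {self.seed})",
            f"derivative order for index features: {self.model.derivative_order}",
            "",
            "Optimized band combinations (calibration subset only):",
            combos.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
            "",
            "Model grid (R2/RMSE on calibration = sim, validation = pre):",
            df.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
            "",
            f"Best model: {b.data_type} + {b.method}  "
            f"(R2_pre={b.r2_pre:.3f}, RMSE_pre={b.rmse_pre:.3f}%, "
            f"RPD={b.rpd:.3f} [{b.rpd_class}])",
        ]
        if self.order_summary is not None:
            lines += [
                "",
                "Derivative-order scan (calibration subset):",
                self.order_summary.to_string(index=False, float_format=lambda x: f"{x:.3f}"),
            ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write the report grid, band combos and a provenance JSON."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reports_frame().to_csv(out / "model_grid.csv", index=False)
        self.combos_frame().to_csv(out / "band_combos.csv", index=False)
        if self.order_summary is not None:
            self.order_summary.to_csv(out / "order_scan.csv", index=False)
        meta = {
            "seed": self.seed,
            "train_ids": list(self.train_ids),
            "val_ids": list(self.val_ids),
            "derivative_order": self.model.derivative_order,
            "alpha": self.model.alpha,
            "configs": {k: asdict(v) for k, v in self.model.configs.items()},
        }
        (out / "provenance.json").write_text(json.dumps(meta, indent=2))
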