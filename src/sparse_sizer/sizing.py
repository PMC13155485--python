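"""Clustered-regression particle-size estimation.

A synthetic library of [X1, X2, X3, X4] metric vectors is computed with the
Monte Carlo engine over a grid of particle radius ``a``, reduced scattering
``μs′``, absorption fraction ``μa/μs′`` and refractive contrast ``n_rel``.
Because the metric-to-size relation changes shape across this space, the
estimator first partitions the standardized metric space by k-means (k
chosen by silhouette score), then fits a stepwise regression of size on the
metrics and their pairwise interactions within each cluster; prediction is
nearest-centroid cluster assignment followed by evaluation of that
cluster's equation.  The low-turbidity cluster uses a linear response in
``a``; the others regress ``log a`` ("exponential" size equations).

Refractive-contrast switching needs no user input: when the cross-envelope
peak sits further than half the equivalent contour radius from the centroid
(peak_radial_fraction > 0.5), the low-n_rel model set is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm_api
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from . import mie as mie_mod
from . import montecarlo as mc
from .metrics import MetricVector, extract_metrics

__all__ = [
    "LibraryEntry",
    "LibraryGrid",
    "SizeEstimate",
    "ClusteredSizeRegressor",
    "ModelSet",
    "build_library",
    "library_to_frame",
    "fit_clusters",
    "fit_size_equations",
    "predict_size",
]

METRIC_NAMES = ["X1", "X2", "X3", "X4"]
INTERACTIONS = [("X1", "X2"), ("X1", "X3"), ("X1", "X4"),
                ("X2", "X3"), ("X2", "X4"), ("X3", "X4")]

RADIUS_RANGE = (10e-9, 10e-6)
MUSP_RANGE = (0.25, 4.0)
MUA_FRACTION_MAX = 0.7


@dataclass
class LibraryEntry:
    radius_a: float  # m
    mu_a: float  # 1/mm
    mu_s_prime: float  # 1/mm
    n_rel: float
    metrics: MetricVector
    sim_seed: int

    def __post_init__(self) -> None:
        lo, hi = RADIUS_RANGE
        if not (lo <= self.radius_a <= hi * (1 + 1e-9)):
            raise ValueError("radius outside the library range")
        if not (MUSP_RANGE[0] <= self.mu_s_prime <= MUSP_RANGE[1] + 1e-9):
            raise ValueError("mu_s_prime outside the library range")
        if self.mu_a < 0 or self.mu_a > MUA_FRACTION_MAX * self.mu_s_prime + 1e-9:
            raise ValueError("mu_a outside the library range")


@dataclass(frozen=True)
class LibraryGrid:
    """Simulation grid for the library build.

    Defaults: 24 log-spaced radii over the full 10 nm – 10 μm range, five
    μs′ values spanning soft-tissue turbidity, four absorption fractions,
    and the biologically relevant n_rel ladder.
    """

    radii: tuple = tuple(np.geomspace(*RADIUS_RANGE, 24))
    mu_s_primes: tuple = (0.25, 0.5, 1.0, 2.0, 4.0)
    mua_fractions: tuple = (0.0, 0.2, 0.45, 0.7)
    n_rels: tuple = (1.03, 1.067, 1.1, 1.2)
    n_medium: float = 1.33
    wavelength: float = 633e-9
    viscosity: float = 1.0e-3  # Pa·s
    temperature: float = 293.15  # K


@dataclass
class SizeEstimate:
    radius_a: float  # m
    cluster_id: int
    distance_to_centroid: float
    n_rel_model_used: float
    extrapolation_flag: bool = False
    valid: bool = True


def _point_seed(base_seed: int, idx: int) -> int:
    # stable per-point stream (Knuth multiplicative hash), kept below 2^31
    return (int(base_seed) * 2654435761 + idx * 9973 + 1) & 0x7FFFFFFF


def build_library(
    grid: LibraryGrid | None = None,
    base_seed: int = 0,
    n_photons: int = 10000,
    max_path_lstar: float = 300.0,
    sim_smooth_px: float = 2.5,
    contour_max_harmonic: int = 12,
    progress: bool = False,
) -> list[LibraryEntry]:
    """Simulate one LibraryEntry per grid point.

    μs′ variation is realized by scaling the scatterer concentration (the
    bulk μs) at fixed particle size — n_rel stays untouched.  Each point
    gets a deterministic seed derived from ``base_seed``; degenerate
    simulations (no detected photons in a channel) are dropped.
    """
    grid = grid or LibraryGrid()
    entries: list[LibraryEntry] = []
    idx = 0
    for n_rel in grid.n_rels:
        for a in grid.radii:
            susp = mie_mod.SphereSuspension(
                radius_a=float(a),
                n_particle=grid.n_medium * n_rel,
                n_medium=grid.n_medium,
                wavelength_vacuum=grid.wavelength,
            )
            mie_res = mie_mod.scattering_quantities(susp)
            D = mie_mod.stokes_einstein_D(float(a), grid.viscosity, grid.temperature)
            for musp in grid.mu_s_primes:
                mu_s = musp / (1.0 - mie_res.anisotropy_g)
                for frac in grid.mua_fractions:
                    seed = _point_seed(base_seed, idx)
                    idx += 1
                    medium = mc.TransportMedium(
                        mu_s=mu_s,
                        mu_a=frac * musp,
                        mie=mie_res,
                        wavenumber=susp.wavenumber_medium,
                        motion=mc.MotionModel(kind="diffusive", D=D),
                    )
                    # the diffuse envelope scales with l* = 1/μs′; widen the
                    # detection grid so the 30% contour stays closed
                    cfg = mc.SimConfig(
                        n_photons=n_photons,
                        rng_seed=seed,
                        max_path_lstar=max_path_lstar,
                        grid_extent=max(4.0, 8.0 / musp),
                    )
                    det = mc.run_simulation(cfg, medium)
                    if det.degenerate:
                        continue
                    try:
                        mv = extract_metrics(
                            det, det,
                            sim_smooth_px=sim_smooth_px,
                            max_harmonic=contour_max_harmonic,
                            polarization_axis_deg=90.0,
                        )
                    except ValueError:
                        continue  # clipped/degenerate envelope at this point
                    entries.append(
                        LibraryEntry(
                            radius_a=float(a),
                            mu_a=frac * musp,
                            mu_s_prime=musp,
                            n_rel=n_rel,
                            metrics=mv,
                            sim_seed=seed,
                        )
                    )
                    if progress:
                        print(
                            f"[library] a={a*1e9:9.1f} nm musp={musp:4.2f} "
                            f"mua/musp={frac:4.2f} n_rel={n_rel:5.3f} -> "
                            f"X=[{mv.X1:.3f} {mv.X2:.3f} {mv.X3:.3f} {mv.X4:.3f}]",
                            flush=True,
                        )
    return entries


def library_to_frame(entries: list[LibraryEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "radius_a": e.radius_a,
                "mu_a": e.mu_a,
                "mu_s_prime": e.mu_s_prime,
                "n_rel": e.n_rel,
                "X1": e.metrics.X1,
                "X2": e.metrics.X2,
                "X3": e.metrics.X3,
                "X4": e.metrics.X4,
                "peak_radial_fraction": e.metrics.peak_radial_fraction,
                "sim_seed": e.sim_seed,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# stepwise regression
# --------------------------------------------------------------------------


def _design_matrix(X: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(X, columns=METRIC_NAMES)
    for a, b in INTERACTIONS:
        df[f"{a}*{b}"] = df[a] * df[b]
    return df


def _stepwise_ols(
    design: pd.DataFrame,
    y: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    criterion: str = "pvalue",
    max_terms: int | None = None,
):
    """Bidirectional stepwise OLS term selection.

    ``criterion="pvalue"``: add the candidate with the smallest partial
    p-value below ``p_enter``, then drop any included term whose p-value
    exceeds ``p_remove``.  ``criterion="aic"``: add/drop while AIC improves.
    Returns the fitted statsmodels result and the selected term list.
    """
    if max_terms is None:
        max_terms = max(1, len(y) // 10)
    selected: list[str] = []
    candidates = list(design.columns)

    def fit(terms):
        Xd = sm_api.add_constant(design[terms].to_numpy()) if terms else np.ones((len(y), 1))
        return sm_api.OLS(y, Xd).fit()

    current = fit(selected)
    for _ in range(3 * len(candidates)):
        changed = False
        # forward (skip once the fit is numerically exact)
        if len(selected) < max_terms and (not selected or current.rsquared < 1 - 1e-12):
            best_term, best_stat = None, None
            for term in candidates:
                if term in selected:
                    continue
                trial = fit(selected + [term])
                if np.isnan(trial.params).any():
                    continue
                if criterion == "aic":
                    stat = trial.aic
                    better = best_stat is None or stat < best_stat
                    accept = trial.aic < current.aic - 1e-9
                else:
                    stat = trial.pvalues[-1]
                    better = best_stat is None or stat < best_stat
                    accept = stat < p_enter
                if accept and better:
                    best_term, best_stat = term, stat
            if best_term is not None:
                selected.append(best_term)
                current = fit(selected)
                changed = True
        # backward
        while selected:
            trial = current
            pvals = trial.pvalues[1:]  # skip intercept
            if criterion == "aic":
                best_drop, best_aic = None, current.aic
                for i, term in enumerate(selected):
                    reduced = fit([t for t in selected if t != term])
                    if reduced.aic < best_aic - 1e-9:
                        best_drop, best_aic = term, reduced.aic
                if best_drop is None:
                    break
                selected.remove(best_drop)
                current = fit(selected)
                changed = True
            else:
                worst = int(np.argmax(pvals))
                if pvals[worst] <= p_remove:
                    break
                selected.pop(worst)
                current = fit(selected)
                changed = True
        if not changed:
            break
    return current, selected


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------


class ClusteredSizeRegressor(BaseEstimator, RegressorMixin):
    """k-means-clustered stepwise regression of particle radius on X1–X4.

    Parameters
    ----------
    k_range : iterable of int
        Candidate cluster counts; the silhouette-maximizing k wins (ties go
        to the smaller k).
    n_init : int
        k-means restarts per candidate k.
    p_enter, p_remove : float
        Partial p-value thresholds of the bidirectional stepwise selection.
    criterion : {"pvalue", "aic"}
        Stepwise selection criterion.
    linear_cluster : {"auto", "none"} or int
        Which cluster regresses ``a`` linearly instead of ``log a``:
        "auto" picks the lowest-median-turbidity cluster when per-entry
        μs′ values are passed to :meth:`fit`; an int forces a cluster id.
    random_state : int
        Seed for k-means.

    Attributes (after fit)
    ----------------------
    scaler_ : fitted StandardScaler over the four metrics.
    kmeans_ : fitted KMeans at the selected k.
    k_, silhouette_ : selected cluster count and its mean silhouette.
    labels_ : training cluster assignment.
    equations_ : per-cluster dict {form, terms, coef, intercept, r2, n}.
    bbox_ : per-cluster (min, max) metric bounds (+10%) for the
        extrapolation flag.
    """

    def __init__(
        self,
        k_range=(2, 3, 4, 5, 6, 7, 8),
        n_init=10,
        p_enter=0.05,
        p_remove=0.10,
        criterion="pvalue",
        linear_cluster="auto",
        min_cluster_size=10,
        random_state=0,
    ):
        self.k_range = k_range
        self.n_init = n_init
        self.p_enter = p_enter
        self.p_remove = p_remove
        self.criterion = criterion
        self.linear_cluster = linear_cluster
        self.min_cluster_size = min_cluster_size
        self.random_state = random_state

    # -- clustering -------------------------------------------------------

    def _fit_clusters(self, Z: np.ndarray) -> None:
        best = None
        for k in self.k_range:
            if k >= len(Z):
                continue
            km = KMeans(n_clusters=k, n_init=self.n_init, random_state=self.random_state)
            labels = km.fit_predict(Z)
            if len(np.unique(labels)) < 2:
                continue
            # a cluster below min_cluster_size cannot support even a
            # one-term equation (fit_N >= 10 per term), so reject this k
            # when the sample is large enough to demand it
            min_size = min(self.min_cluster_size, max(2, len(Z) // 10))
            if np.bincount(labels).min() < min_size:
                continue
            score = silhouette_score(Z, labels)
            # strict '>' keeps the smaller k on ties
            if best is None or score > best[0] + 1e-12:
                best = (score, k, km, labels)
        if best is None:
            raise ValueError("could not cluster: need at least 2 distinct entries")
        self.silhouette_, self.k_, self.kmeans_, self.labels_ = best

    def fit(self, X, y, mu_s_prime=None):
        """Fit clusters and per-cluster size equations.

        X : (n, 4) metric vectors; y : radii in meters; ``mu_s_prime``
        optionally tags each entry's turbidity for the linear-cluster rule.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be (n_samples, 4) metric vectors")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("metrics must be finite and radii positive")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self._fit_clusters(Z)

        if self.linear_cluster == "none" or mu_s_prime is None and self.linear_cluster == "auto":
            linear_id = -1
        elif self.linear_cluster == "auto":
            musp = np.asarray(mu_s_prime, dtype=float)
            medians = [
                np.median(musp[self.labels_ == c]) if np.any(self.labels_ == c) else np.inf
                for c in range(self.k_)
            ]
            linear_id = int(np.argmin(medians))
        else:
            linear_id = int(self.linear_cluster)
        self.linear_cluster_id_ = linear_id

        design = _design_matrix(X)
        self.equations_ = {}
        self.bbox_ = {}
        for c in range(self.k_):
            mask = self.labels_ == c
            n_c = int(mask.sum())
            form = "linear" if c == linear_id else "exponential"
            # a linear response is only adequate over a narrow size range;
            # a cluster spanning decades falls back to the log form
            if form == "linear" and np.ptp(np.log10(y[mask])) > 1.5:
                form = "exponential"
            resp = y[mask] if form == "linear" else np.log(y[mask])
            max_terms = max(1, n_c // 10)
            res, terms = _stepwise_ols(
                design[mask],
                resp,
                p_enter=self.p_enter,
                p_remove=self.p_remove,
                criterion=self.criterion,
                max_terms=max_terms,
            )
            self.equations_[c] = {
                "form": form,
                "terms": terms,
                "intercept": float(res.params[0]),
                "coef": [float(v) for v in res.params[1:]],
                "r2": float(res.rsquared) if n_c > len(terms) + 1 else 1.0,
                "n": n_c,
            }
            lo = X[mask].min(axis=0)
            hi = X[mask].max(axis=0)
            pad = 0.10 * (hi - lo)
            self.bbox_[c] = (lo - pad, hi + pad)
        return self

    # -- prediction -------------------------------------------------------

    def _evaluate_equation(self, cluster: int, x: np.ndarray) -> float:
        eq = self.equations_[cluster]
        row = _design_matrix(x[None, :]).iloc[0]
        val = eq["intercept"] + sum(
            c * row[t] for c, t in zip(eq["coef"], eq["terms"])
        )
        if eq["form"] == "exponential":
            return float(np.exp(val))
        return float(val)

    def predict_detailed(self, X) -> list[SizeEstimate]:
        check_is_fitted(self, "equations_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if not np.all(np.isfinite(X)):
            raise ValueError("metrics must be finite")
        Z = self.scaler_.transform(X)
        d = np.linalg.norm(Z[:, None, :] - self.kmeans_.cluster_centers_[None], axis=2)
        clusters = np.argmin(d, axis=1)
        out = []
        for x, z_d, c in zip(X, d, clusters):
            a = self._evaluate_equation(int(c), x)
            lo, hi = self.bbox_[int(c)]
            extrap = bool(np.any(x < lo) or np.any(x > hi))
            valid = bool(np.isfinite(a) and a > 0)
            out.append(
                SizeEstimate(
                    radius_a=a if valid else np.nan,
                    cluster_id=int(c),
                    distance_to_centroid=float(z_d[c]),
                    n_rel_model_used=np.nan,
                    extrapolation_flag=extrap,
                    valid=valid,
                )
            )
        return out

    def predict(self, X):
        return np.array([e.radius_a for e in self.predict_detailed(X)])

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "equations_")
        return {
            "params": self.get_params(),
            "k": int(self.k_),
            "silhouette": float(self.silhouette_),
            "centroids": self.kmeans_.cluster_centers_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "linear_cluster_id": int(self.linear_cluster_id_),
            "equations": {str(k): v for k, v in self.equations_.items()},
            "bbox": {str(k): [v[0].tolist(), v[1].tolist()] for k, v in self.bbox_.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusteredSizeRegressor":
        obj = cls(**{k: v for k, v in d["params"].items() if k != "k_range"})
        obj.k_ = d["k"]
        obj.silhouette_ = d["silhouette"]
        obj.scaler_ = StandardScaler()
        obj.scaler_.mean_ = np.array(d["scaler_mean"])
        obj.scaler_.scale_ = np.array(d["scaler_scale"])
        obj.scaler_.var_ = obj.scaler_.scale_ ** 2
        obj.scaler_.n_features_in_ = 4
        obj.kmeans_ = KMeans(n_clusters=obj.k_)
        obj.kmeans_.cluster_centers_ = np.array(d["centroids"])
        obj.linear_cluster_id_ = d["linear_cluster_id"]
        obj.equations_ = {int(k): v for k, v in d["equations"].items()}
        obj.bbox_ = {
            int(k): (np.array(v[0]), np.array(v[1])) for k, v in d["bbox"].items()
        }
        obj.labels_ = None
        return obj


# --------------------------------------------------------------------------
# model sets over n_rel and the functional surface
# --------------------------------------------------------------------------


@dataclass
class ModelSet:
    """Size models trained independently per n_rel tag.

    The prediction rule consults only the measured cross-envelope peak
    location: peak_radial_fraction > 0.5 selects the lowest-n_rel model,
    otherwise the tag closest to the tissue-average 1.1 is used.
    """

    models: dict[float, ClusteredSizeRegressor]
    default_tag: float | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("need at least one trained model")
        if self.default_tag is None:
            tags = np.array(sorted(self.models))
            self.default_tag = float(tags[np.argmin(np.abs(tags - 1.1))])

    @property
    def low_tag(self) -> float:
        return float(min(self.models))

    def select(self, peak_radial_fraction: float) -> float:
        return self.low_tag if peak_radial_fraction > 0.5 else self.default_tag

    def to_json(self, path) -> None:
        payload = {
            "default_tag": self.default_tag,
            "models": {str(tag): m.to_dict() for tag, m in self.models.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            models={
                float(tag): ClusteredSizeRegressor.from_dict(d)
                for tag, d in payload["models"].items()
            },
            default_tag=payload["default_tag"],
        )


def fit_clusters(entries: list[LibraryEntry], k_range=(2, 3, 4, 5, 6, 7, 8),
                 random_state: int = 0) -> ClusteredSizeRegressor:
    """Cluster a library's metric space (clusters only; equations unfitted)."""
    df = library_to_frame(entries)
    est = ClusteredSizeRegressor(k_range=k_range, random_state=random_state)
    X = df[METRIC_NAMES].to_numpy()
    est.scaler_ = StandardScaler().fit(X)
    est._fit_clusters(est.scaler_.transform(X))
    return est


def fit_size_equations(
    entries: list[LibraryEntry],
    k_range=(2, 3, 4, 5, 6, 7, 8),
    random_state: int = 0,
    **kw,
) -> ClusteredSizeRegressor:
    """Full fit: clusters plus per-cluster stepwise size equations."""
    df = library_to_frame(entries)
    est = ClusteredSizeRegressor(k_range=k_range, random_state=random_state, **kw)
    est.fit(
        df[METRIC_NAMES].to_numpy(),
        df["radius_a"].to_numpy(),
        mu_s_prime=df["mu_s_prime"].to_numpy(),
    )
    return est


def predict_size(metrics: MetricVector, models: ModelSet) -> SizeEstimate:
    """Predict radius for one measured metric vector, with the n_rel switch."""
    tag = models.select(metrics.peak_radial_fraction)
    est = models.models[tag].predict_detailed(metrics.as_array())[0]
    est.n_rel_model_used = tag
    return est
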