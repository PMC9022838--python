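"""Weighted least-squares flux fitting against MID measurements.

Measurements are records (tracer, metabolite, mass isotopomer, value,
sd, replicate) tagged as estimation or validation data.  The objective is
the sum of squared sigma-weighted residuals

    SSR(u) = sum_ij ((yhat_ij - y_ij) / sigma_ij)^2

minimized over free fluxes u subject to K u >= 0, lb <= u <= ub and an
optional normalization equality (one uptake flux pinned to 1).  Replicates
are aggregated to means weighted by the standard error of the mean before
fitting; multistart SLSQP with analytic EMU sensitivities does the local
optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.optimize

from .emu_engine import EMUCascade, TracerSpec, full_emu, measured_cascade
from .network_model import FluxParameterization, NetworkModel

__all__ = [
    "MeasurementSet",
    "NoiseSpec",
    "FitResult",
    "FitConfig",
    "MFAProblem",
    "ssr",
    "sem",
    "aggregate_replicates",
    "fit",
]

COLUMNS = [
    "tracer", "metabolite", "mass_isotopomer", "value", "sd",
    "n_replicates", "replicate", "split",
]


@dataclass(frozen=True)
class NoiseSpec:
    """True (sigma_r) vs believed (sigma_b) measurement standard deviations."""

    sigma_r: np.ndarray
    sigma_b: np.ndarray

    def __post_init__(self):
        if (np.asarray(self.sigma_r) <= 0).any() or (np.asarray(self.sigma_b) <= 0).any():
            raise ValueError("all standard deviations must be positive")


@dataclass
class MeasurementSet:
    """A table of MID (or generic output) measurements.

    Wraps a DataFrame with columns tracer, metabolite, mass_isotopomer,
    value, sd, n_replicates, replicate, split.  `split` is 'est' or 'val'.
    """

    data: pd.DataFrame

    def __post_init__(self):
        missing = set(COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"measurement table lacks columns {sorted(missing)}")
        if (self.data["sd"] <= 0).any():
            raise ValueError("sd must be positive for every record")
        bad = set(self.data["split"]) - {"est", "val"}
        if bad:
            raise ValueError(f"unknown split tags {bad}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "MeasurementSet":
        df = pd.DataFrame.from_records(records)
        for col, default in (("n_replicates", 1), ("replicate", 0),
                             ("split", "est"), ("mass_isotopomer", 0)):
            if col not in df.columns:
                df[col] = default
        return cls(df[COLUMNS].copy())

    def subset(self, split: str) -> "MeasurementSet":
        return MeasurementSet(self.data[self.data["split"] == split].reset_index(drop=True))

    def with_sigma(self, sigma: np.ndarray) -> "MeasurementSet":
        df = self.data.copy()
        df["sd"] = np.asarray(sigma, float)
        return MeasurementSet(df)

    def __len__(self) -> int:
        return len(self.data)

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MeasurementSet":
        df = pd.read_csv(path)
        for col, default in (("n_replicates", 1), ("replicate", 0), ("split", "est")):
            if col not in df.columns:
                df[col] = default
        return cls(df[COLUMNS].copy())


def sem(sigma: float, N: int) -> float:
    """Standard error of the mean, sigma / sqrt(N)."""
    if N < 1:
        raise ValueError("replicate count must be >= 1")
    return sigma / np.sqrt(N)


def aggregate_replicates(data: MeasurementSet) -> MeasurementSet:
    """Average replicates; weights become the standard error of the mean.

    Records sharing (tracer, metabolite, mass_isotopomer, split) are
    replaced by their mean with sd -> sd / sqrt(n).  The stated sd must be
    identical within a group (it is the per-observation sigma).
    """
    df = data.data
    keys = ["tracer", "metabolite", "mass_isotopomer", "split"]
    agg = df.groupby(keys, sort=False).agg(
        value=("value", "mean"),
        sd=("sd", "mean"),
        n=("value", "size"),
    ).reset_index()
    agg["sd"] = agg["sd"] / np.sqrt(agg["n"])
    agg["n_replicates"] = agg["n"]
    agg["replicate"] = 0
    return MeasurementSet(agg[COLUMNS].copy())


def ssr(predicted: np.ndarray | dict, data: MeasurementSet,
        sigma: np.ndarray | None = None) -> float:
    """Sum of squared weighted residuals against `data`.

    `predicted` is either a vector aligned with the data rows, or a
    {(tracer, metabolite): MID} mapping from which rows are resolved.
    """
    df = data.data
    if isinstance(predicted, dict):
        yhat = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            key = (row.tracer, row.metabolite)
            if key not in predicted:
                raise KeyError(f"no prediction for {key}")
            yhat[i] = predicted[key][int(row.mass_isotopomer)]
    else:
        yhat = np.asarray(predicted, float)
        if yhat.shape != (len(df),):
            raise ValueError("prediction vector length mismatch")
    sig = df["sd"].to_numpy() if sigma is None else np.asarray(sigma, float)
    r = (yhat - df["value"].to_numpy()) / sig
    return float(r @ r)


@dataclass
class FitConfig:
    n_starts: int = 20
    seed: int = 0
    maxiter: int = 2000
    ftol: float = 1e-9
    ub: float = 100.0
    lb: float = 0.0
    aggregate: bool = True  # SEM-weighted replicate means (stacking if False)


@dataclass
class FitResult:
    u_star: np.ndarray
    v_star: np.ndarray
    ssr_star: float
    residuals: np.ndarray
    n_starts: int
    n_converged: int
    seed: int
    start_values: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "u_star": self.u_star.tolist(),
            "v_star": self.v_star.tolist(),
            "ssr": self.ssr_star,
            "residuals": self.residuals.tolist(),
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "seed": self.seed,
        }


class MFAProblem:
    """A network model bound to tracers and a measurement layout.

    Compiles the EMU cascade, the flux parameterization (one uptake flux
    normalized to 1), analytic sensitivities, and the index arrays mapping
    measurement rows to cascade state entries; provides fast SSR and
    gradient callables for the optimizer, profile machinery and MCMC.
    """

    def __init__(
        self,
        model: NetworkModel,
        tracers: list[TracerSpec],
        normalized_flux: str | None = None,
        ub: float = 100.0,
    ):
        self.model = model
        self.tracers = list(tracers)
        self.tracer_index = {t.name: i for i, t in enumerate(self.tracers)}
        self.cascade = measured_cascade(model)
        self.param = FluxParameterization.from_model(
            model, lb=0.0, ub=ub, fixed_flux=normalized_flux
        )
        self.sens = self.cascade.compile_sensitivities(self.param.K)
        self._vertices: np.ndarray | None = None

    @property
    def n_free_parameters(self) -> int:
        return self.param.n_free_parameters

    # -- measurement binding ------------------------------------------

    def bind(self, data: MeasurementSet, aggregate: bool = True) -> "_BoundData":
        if aggregate:
            data = aggregate_replicates(data)
        df = data.data
        locs = []
        for row in df.itertuples(index=False):
            bi, r = self.cascade.locate(full_emu(self.model, row.metabolite))
            locs.append((self.tracer_index[row.tracer], bi, r, int(row.mass_isotopomer)))
        return _BoundData(
            problem=self,
            data=data,
            t_idx=np.array([l[0] for l in locs]),
            b_idx=np.array([l[1] for l in locs]),
            r_idx=np.array([l[2] for l in locs]),
            m_idx=np.array([l[3] for l in locs]),
            y=df["value"].to_numpy(float),
            sigma=df["sd"].to_numpy(float),
        )

    # -- prediction ----------------------------------------------------

    def predict_mids(self, v: np.ndarray) -> dict[tuple[str, str], np.ndarray]:
        """{(tracer name, metabolite): MID} at flux vector v."""
        sols = self.cascade.simulate(v, self.tracers)
        out = {}
        for tr, sol in zip(self.tracers, sols):
            for t in self.cascade.targets:
                out[(tr.name, t.metabolite)] = sol[t]
        return out

    # -- feasible starts ----------------------------------------------

    def _vertex_cache(self, rng: np.ndarray) -> np.ndarray:
        if self._vertices is None:
            K = self.param.K
            p = K.shape[1]
            A_ub = -K
            b_ub = np.zeros(K.shape[0])
            bounds = [(self.param.lb, self.param.ub)] * p
            A_eq = b_eq = None
            if self.param.fixed_index is not None:
                A_eq = K[self.param.fixed_index][None, :]
                b_eq = np.array([1.0])
            verts = []
            vert_rng = np.random.default_rng(12345)  # cache is start-independent
            tries = 0
            while len(verts) < max(2 * p, 12) and tries < 20 * p:
                tries += 1
                c = vert_rng.standard_normal(p)
                res = scipy.optimize.linprog(
                    c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                    method="highs",
                )
                if res.success:
                    verts.append(res.x)
            if not verts:
                raise RuntimeError("no feasible start found for the flux cone")
            self._vertices = np.unique(np.round(np.array(verts), 9), axis=0)
        return self._vertices

    def sample_starts(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Interior feasible starts as Dirichlet mixtures of cone vertices."""
        verts = self._vertex_cache(rng)
        W = rng.dirichlet(np.ones(len(verts)), size=n)
        return W @ verts

    # -- fitting -------------------------------------------------------

    def fit(self, data: MeasurementSet, config: FitConfig | None = None) -> FitResult:
        config = config or FitConfig()
        bound = self.bind(data, aggregate=config.aggregate)
        rng = np.random.default_rng(config.seed)
        starts = self.sample_starts(config.n_starts, rng)
        cons = [{"type": "ineq",
                 "fun": lambda u: self.param.K @ u,
                 "jac": lambda u: self.param.K}]
        if self.param.fixed_index is not None:
            row = self.param.K[self.param.fixed_index]
            cons.append({"type": "eq",
                         "fun": lambda u, row=row: row @ u - 1.0,
                         "jac": lambda u, row=row: row[None, :]})
        bounds = [(self.param.lb, self.param.ub)] * self.param.nullity
        best = None
        n_conv = 0
        start_values = []
        for x0 in starts:
            try:
                res = scipy.optimize.minimize(
                    bound.ssr_and_grad, x0, jac=True, method="SLSQP",
                    bounds=bounds, constraints=cons,
                    options={"maxiter": config.maxiter, "ftol": config.ftol},
                )
            except Exception:
                continue
            if not np.isfinite(res.fun):
                continue
            n_conv += int(res.success)
            start_values.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("all optimization starts failed")
        u = best.x
        yhat = bound.predict(u)
        return FitResult(
            u_star=u,
            v_star=self.param.fluxes(u),
            ssr_star=float(best.fun),
            residuals=(yhat - bound.y) / bound.sigma,
            n_starts=config.n_starts,
            n_converged=n_conv,
            seed=config.seed,
            start_values=start_values,
        )


@dataclass
class _BoundData:
    """Measurement rows mapped to cascade state indices for one problem."""

    problem: MFAProblem
    data: MeasurementSet
    t_idx: np.ndarray
    b_idx: np.ndarray
    r_idx: np.ndarray
    m_idx: np.ndarray
    y: np.ndarray
    sigma: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    def predict(self, u: np.ndarray) -> np.ndarray:
        v = self.problem.param.fluxes(u)
        X, _, _ = self.problem.cascade._solve(v, self.problem.tracers, strict=False)
        return np.array(
            [X[b][r, m, t] for t, b, r, m in
             zip(self.t_idx, self.b_idx, self.r_idx, self.m_idx)]
        )

    def predict_with_grad(self, u: np.ndarray):
        X, dX = self.problem.sens.simulate(u, self.problem.tracers)
        yhat = np.array(
            [X[b][r, m, t] for t, b, r, m in
             zip(self.t_idx, self.b_idx, self.r_idx, self.m_idx)]
        )
        J = np.stack(
            [dX[b][:, r, m, t] for t, b, r, m in
             zip(self.t_idx, self.b_idx, self.r_idx, self.m_idx)]
        )
        return yhat, J  # J: (n_records, p)

    def ssr_value(self, u: np.ndarray) -> float:
        r = (self.predict(u) - self.y) / self.sigma
        return float(r @ r)

    def ssr_and_grad(self, u: np.ndarray):
        yhat, J = self.predict_with_grad(u)
        r = (yhat - self.y) / self.sigma
        return float(r @ r), 2.0 * (J.T @ (r / self.sigma))


def fit(
    model: NetworkModel,
    data: MeasurementSet,
    tracers: list[TracerSpec],
    config: FitConfig | None = None,
    normalized_flux: str | None = None,
) -> FitResult:
    """Multistart constrained WLS fit of `model` to the estimation split."""
    problem = MFAProblem(model, tracers, normalized_flux=normalized_flux,
                         ub=(config.ub if config else 100.0))
    est = data.subset("est") if "val" in set(data.data["split"]) else data
    return problem.fit(est, config)
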