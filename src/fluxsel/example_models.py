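"""Benchmark model families for validation-based model selection studies.

Three families of nested candidate models:

* polynomials h1..h14 on a fixed 20-point design over [-1, 1], with a
  degree-7 generating truth;
* linear maps A1..A6, 3x3 matrices whose free-entry sets are nested, with
  a diagonal generating truth A3;
* seven nested metabolic network models m1..m7 of a compartment-free TCA
  cycle with glutamine and pyruvate uptake, shipped as model files with
  four tracers and a feasible generating flux vector for m4.

The truths are shipped constants; all recovery tests target them.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .emu_engine import TracerSpec
from .network_model import NetworkModel, parse_model_text

__all__ = [
    "PolynomialModel",
    "LinearModel",
    "TCAModelFamily",
    "get_polynomial_family",
    "get_linear_family",
    "get_tca_family",
    "polynomial_design",
    "linear_inputs",
    "true_polynomial_coefficients",
    "true_linear_parameters",
    "LINEAR_SLOTS",
]

# 20 evenly spaced abscissae; every fifth point is held out for validation.
N_POLY_POINTS = 20
POLY_VALIDATION_STRIDE = 5

# Free-entry positions (row, col) of the nested 3x3 linear maps: A_k uses
# the first k slots, so the parameter space of A_k contains that of A_l, l<k.
LINEAR_SLOTS = [(0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2)]

# Six distinct 3-vectors probing single and combined inputs; the last two
# are reserved for validation.
LINEAR_INPUTS = np.array(
    [
        [3.0, 0.0, 0.0],
        [0.0, 3.0, 0.0],
        [0.0, 0.0, 3.0],
        [3.0, 3.0, 0.0],
        [0.0, 3.0, 3.0],
        [3.0, 3.0, 3.0],
    ]
)
N_LINEAR_VALIDATION_INPUTS = 2


def polynomial_design() -> np.ndarray:
    """The fixed x design: 20 evenly spaced points on [-1, 1]."""
    return np.linspace(-1.0, 1.0, N_POLY_POINTS)


def polynomial_validation_mask() -> np.ndarray:
    """Boolean mask over the design marking the 4 validation points."""
    idx = np.arange(N_POLY_POINTS)
    return idx % POLY_VALIDATION_STRIDE == 0


def linear_inputs() -> np.ndarray:
    return LINEAR_INPUTS.copy()


def linear_validation_mask() -> np.ndarray:
    """Boolean mask over the 6 inputs marking the 2 validation inputs."""
    mask = np.zeros(len(LINEAR_INPUTS), dtype=bool)
    mask[-N_LINEAR_VALIDATION_INPUTS:] = True
    return mask


def _manifest() -> dict:
    text = (resources.files("fluxsel") / "models" / "manifest.json").read_text()
    return json.loads(text)


def true_polynomial_coefficients() -> np.ndarray:
    """Shipped degree-7 generating coefficients (low order first)."""
    return np.asarray(_manifest()["true_polynomial_coefficients"], float)


def true_linear_parameters() -> np.ndarray:
    """Shipped generating parameters of the diagonal map A3."""
    return np.asarray(_manifest()["true_linear_parameters"], float)


@dataclass(frozen=True)
class PolynomialModel:
    """Polynomial predictor h_n(x, u) = sum_k u_k x^k of order `order`."""

    order: int

    @property
    def model_id(self) -> str:
        return f"h{self.order:02d}"

    @property
    def n_params(self) -> int:
        return self.order + 1

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return x[:, None] ** np.arange(self.order + 1)

    def evaluate(self, x: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
        return self.design(x) @ np.asarray(coefficients, float)

    def _xy(self, data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        df = data.data
        x = polynomial_design()[df["mass_isotopomer"].to_numpy(int)]
        return x, df["value"].to_numpy(float), df["sd"].to_numpy(float)

    def fit(self, data) -> tuple[np.ndarray, float]:
        """Closed-form weighted least squares; returns (coefficients, ssr)."""
        x, y, sd = self._xy(data)
        V = self.design(x)
        coef, *_ = np.linalg.lstsq(V / sd[:, None], y / sd, rcond=None)
        r = (V @ coef - y) / sd
        return coef, float(r @ r)

    def ssr(self, coefficients: np.ndarray, data) -> float:
        x, y, sd = self._xy(data)
        r = (self.evaluate(x, coefficients) - y) / sd
        return float(r @ r)


@dataclass(frozen=True)
class LinearModel:
    """Linear map y = A_k x with k free entries in nested slot order."""

    k: int

    @property
    def model_id(self) -> str:
        return f"A{self.k}"

    @property
    def n_params(self) -> int:
        return self.k

    @property
    def slots(self) -> list[tuple[int, int]]:
        return LINEAR_SLOTS[: self.k]

    def matrix(self, a: np.ndarray) -> np.ndarray:
        A = np.zeros((3, 3))
        for val, (r, c) in zip(np.asarray(a, float), self.slots):
            A[r, c] = val
        return A

    def evaluate(self, x: np.ndarray, a: np.ndarray) -> np.ndarray:
        return self.matrix(a) @ np.asarray(x, float)

    def _design_rows(self, data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        df = data.data
        inputs = LINEAR_INPUTS
        j = df["tracer"].str.removeprefix("x").to_numpy(int)
        out_row = df["mass_isotopomer"].to_numpy(int)
        D = np.zeros((len(df), self.k))
        for i, (r, c) in enumerate(self.slots):
            D[:, i] = np.where(out_row == r, inputs[j, c], 0.0)
        return D, df["value"].to_numpy(float), df["sd"].to_numpy(float)

    def fit(self, data) -> tuple[np.ndarray, float]:
        """Closed-form weighted least squares; returns (parameters, ssr)."""
        D, y, sd = self._design_rows(data)
        a, *_ = np.linalg.lstsq(D / sd[:, None], y / sd, rcond=None)
        r = (D @ a - y) / sd
        return a, float(r @ r)

    def ssr(self, a: np.ndarray, data) -> float:
        D, y, sd = self._design_rows(data)
        r = (D @ np.asarray(a, float) - y) / sd
        return float(r @ r)


def get_polynomial_family() -> list[PolynomialModel]:
    """Candidate polynomials of order 1 through 14."""
    return [PolynomialModel(n) for n in range(1, 15)]


def get_linear_family() -> list[LinearModel]:
    """Candidate linear maps A1 through A6."""
    return [LinearModel(k) for k in range(1, 7)]


@dataclass
class TCAModelFamily:
    """Seven nested network models plus tracers and shipped truths."""

    models: dict[str, NetworkModel]
    additions: dict[str, list[str]]
    tracers: dict[str, TracerSpec]
    estimation_tracers: list[str]
    validation_tracer: str
    true_model: str
    true_fluxes: dict[str, float]
    normalized_flux: str
    manifest: dict = field(repr=False, default_factory=dict)

    @property
    def model_ids(self) -> list[str]:
        return list(self.models)

    def true_flux_vector(self, model_id: str | None = None) -> np.ndarray:
        """Generating flux vector aligned to `model_id`'s reaction order.

        Reactions absent from the generating model carry zero flux, so the
        same steady state is expressible in every superset model.
        """
        model = self.models[model_id or self.true_model]
        return np.array([self.true_fluxes.get(r.id, 0.0) for r in model.reactions])

    def tracer_list(self, names: list[str]) -> list[TracerSpec]:
        return [self.tracers[n] for n in names]


def get_tca_family() -> TCAModelFamily:
    """Load the shipped nested TCA-cycle model family."""
    base = resources.files("fluxsel") / "models"
    manifest = json.loads((base / "manifest.json").read_text())
    models = {
        mid: parse_model_text((base / f"{mid}.tsv").read_text(), name=mid)
        for mid in manifest["models"]
    }
    tracers = {}
    with io.StringIO((base / "tracers.csv").read_text()) as fh:
        for row in csv.DictReader(fh):
            tracers[row["name"]] = TracerSpec(
                row["name"], row["metabolite"], row["pattern"]
            )
    return TCAModelFamily(
        models=models,
        additions=manifest["additions"],
        tracers=tracers,
        estimation_tracers=list(manifest["estimation_tracers"]),
        validation_tracer=manifest["validation_tracer"],
        true_model=manifest["true_model"],
        true_fluxes=dict(manifest["true_fluxes_m4"]),
        normalized_flux=manifest["normalized_flux"],
        manifest=manifest,
    )
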