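"""EMU decomposition and steady-state MID simulation.

The elementary-metabolite-unit (EMU) framework reduces an atom-mapped
network to the minimal set of state variables needed to simulate the mass
isotopomer distributions (MIDs) of a chosen set of metabolites.  An EMU is
a (metabolite, carbon subset) pair; its state is a MID of length size+1.
Backward traversal from the target EMUs yields, for each EMU size n, a
linear balance system

    A_n(v) X_n = B_n(v) Y_n

where X_n stacks the unknown EMU MIDs of size n, Y_n stacks known inputs
(tracer EMUs, previously solved smaller EMUs, and convolutions thereof
arising at condensation reactions), and A, B are linear in the flux
vector v.  Blocks are solved in increasing size order.

The cascade is compiled once per (model, targets); simulation at a given
flux vector is a handful of small dense solves, and analytic sensitivities
with respect to free fluxes u (v = K u) reuse each block's factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.linalg import lapack as _lapack

from .network_model import NetworkModel

__all__ = [
    "EMU",
    "TracerSpec",
    "EMUCascade",
    "decompose",
    "full_emu",
    "measured_cascade",
    "simulate_mids",
    "convolve",
    "validate_mid",
    "SingularCascadeError",
]


class SingularCascadeError(RuntimeError):
    """A block system A(v) is singular (e.g. zero inflow to an EMU)."""


@dataclass(frozen=True, order=True)
class EMU:
    """A subset of a metabolite's carbon atoms (1-based indices)."""

    metabolite: str
    atoms: tuple[int, ...]  # sorted, 1-based

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(sorted(self.atoms)))
        if not self.atoms:
            raise ValueError("EMU needs at least one atom")

    @property
    def size(self) -> int:
        return len(self.atoms)

    def __str__(self) -> str:
        return f"{self.metabolite}{{{','.join(map(str, self.atoms))}}}"


@dataclass(frozen=True)
class TracerSpec:
    """Positional 13C labelling pattern of one substrate ('1' = 13C)."""

    name: str
    metabolite: str
    pattern: str

    def __post_init__(self):
        if set(self.pattern) - {"0", "1"}:
            raise ValueError(f"tracer pattern must be binary, got {self.pattern!r}")

    def emu_mid(self, emu: EMU) -> np.ndarray:
        """Exact MID of a substrate EMU under this tracer (no natural abundance)."""
        if emu.metabolite != self.metabolite:
            raise ValueError(f"tracer {self.name} does not label {emu.metabolite}")
        n_labeled = sum(self.pattern[i - 1] == "1" for i in emu.atoms)
        mid = np.zeros(emu.size + 1)
        mid[n_labeled] = 1.0
        return mid


def validate_mid(mid: np.ndarray, tol: float = 1e-9) -> bool:
    mid = np.asarray(mid)
    return bool(abs(mid.sum() - 1.0) <= tol and (mid >= -1e-12).all())


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cauchy product of two MIDs (the MID of the condensation product)."""
    return np.convolve(np.asarray(a, float), np.asarray(b, float))


# ----------------------------------------------------------------------
# Decomposition
#
# A Y entry is a tuple of "factors"; each factor is either
#   ("x", EMU)            tracer-supplied substrate EMU
#   ("u", size, row)      unknown EMU solved in an earlier block
# Single-factor entries are plain transfers; multi-factor entries are
# convolutions from condensation reactions.


@dataclass
class _Block:
    size: int
    emus: list[EMU] = field(default_factory=list)
    index: dict[EMU, int] = field(default_factory=dict)
    # assembly triplets (row, col, reaction index, coefficient)
    a_trip: list[tuple[int, int, int, float]] = field(default_factory=list)
    b_trip: list[tuple[int, int, int, float]] = field(default_factory=list)
    y_entries: list[tuple] = field(default_factory=list)
    y_index: dict[tuple, int] = field(default_factory=dict)


class EMUCascade:
    """Size-ordered compiled EMU blocks for one model and target set."""

    def __init__(self, model: NetworkModel, targets: list[EMU]):
        self.model = model
        self.targets = list(targets)
        self.blocks: list[_Block] = []
        self._build()
        self._finalize()

    # -- graph construction -------------------------------------------

    def _producing_terms(self, emu: EMU):
        """Yield (rxn index, weight, factor EMU list) for producers of `emu`."""
        model = self.model
        for j, term in model.producers(emu.metabolite):
            letters = {term.atoms[i - 1] for i in emu.atoms}
            factors: list[EMU] = []
            for rt in model.reactions[j].reactants:
                if rt.atoms is None:
                    continue
                pos = tuple(p + 1 for p, ch in enumerate(rt.atoms) if ch in letters)
                if pos:
                    factors.append(EMU(rt.metabolite, pos))
            if not factors:
                raise ValueError(
                    f"reaction {model.reactions[j].id} produces {emu} "
                    "but supplies no mapped atoms"
                )
            yield j, float(term.coeff), factors

    def _build(self) -> None:
        model = self.model
        seen: set[EMU] = set()
        stack: list[EMU] = []
        for t in self.targets:
            met = model.metabolites.get(t.metabolite)
            if met is None:
                raise ValueError(f"unknown target metabolite {t.metabolite}")
            if met.role != "balanced":
                raise ValueError(f"target {t} is not a balanced metabolite")
            if t not in seen:
                seen.add(t)
                stack.append(t)
        terms: dict[EMU, list] = {}
        while stack:
            emu = stack.pop()
            terms[emu] = []
            producers = list(self._producing_terms(emu))
            if not producers:
                raise ValueError(f"{emu} is unreachable from any substrate")
            for j, w, factors in producers:
                terms[emu].append((j, w, factors))
                for f in factors:
                    role = model.metabolites[f.metabolite].role
                    if role == "substrate":
                        continue
                    if role == "sink":
                        raise ValueError(
                            f"reaction {model.reactions[j].id} consumes sink "
                            f"metabolite {f.metabolite}"
                        )
                    if f not in seen:
                        seen.add(f)
                        stack.append(f)
        self._terms = terms
        self.emus = sorted(terms)  # lexicographic by (metabolite, atoms)

    def _finalize(self) -> None:
        model = self.model
        sizes = sorted({e.size for e in self._terms})
        blocks = {n: _Block(n) for n in sizes}
        for emu in self.emus:
            b = blocks[emu.size]
            b.index[emu] = len(b.emus)
            b.emus.append(emu)

        def factor_ref(f: EMU):
            if model.metabolites[f.metabolite].role == "substrate":
                return ("x", f)
            return ("u", f.size, blocks[f.size].index[f])

        for emu in self.emus:
            b = blocks[emu.size]
            i = b.index[emu]
            # outflow (diagonal): total consumption of the metabolite
            cons = model.consumption(emu.metabolite)
            if not cons:
                raise ValueError(
                    f"metabolite {emu.metabolite} has no consuming reaction; "
                    "its EMU balance is undefined"
                )
            for j, c in cons:
                b.a_trip.append((i, i, j, float(c)))
            for j, w, factors in self._terms[emu]:
                if (
                    len(factors) == 1
                    and factors[0].size == emu.size
                    and model.metabolites[factors[0].metabolite].role == "balanced"
                ):
                    # same-size unknown-to-unknown transfer -> A off-diagonal
                    src = b.index[factors[0]]
                    b.a_trip.append((i, src, j, -w))
                else:
                    key = tuple(factor_ref(f) for f in factors)
                    if key not in b.y_index:
                        b.y_index[key] = len(b.y_entries)
                        b.y_entries.append(key)
                    b.b_trip.append((i, b.y_index[key], j, w))
        self.blocks = [blocks[n] for n in sizes]
        self._size_to_block = {b.size: i for i, b in enumerate(self.blocks)}
        n_flux = len(model.reactions)
        for b in self.blocks:
            b._a_rows, b._a_cols, b._a_flux, b._a_coef = _as_arrays(b.a_trip)
            b._b_rows, b._b_cols, b._b_flux, b._b_coef = _as_arrays(b.b_trip)
            # dense assembly maps: vec(A) = _A_mat @ v, vec(B) = _B_mat @ v
            n = len(b.emus)
            ny = max(len(b.y_entries), 1)
            b._A_mat = np.zeros((n * n, n_flux))
            np.add.at(b._A_mat, (b._a_rows * n + b._a_cols, b._a_flux), b._a_coef)
            b._B_mat = np.zeros((n * ny, n_flux))
            np.add.at(b._B_mat, (b._b_rows * ny + b._b_cols, b._b_flux), b._b_coef)
            # split Y entries by kind for fast evaluation
            b._y_x, b._y_ref, b._y_conv = [], [], []
            for yi, entry in enumerate(b.y_entries):
                if len(entry) == 1 and entry[0][0] == "x":
                    b._y_x.append((yi, entry[0][1]))
                elif len(entry) == 1:
                    _, size, row = entry[0]
                    b._y_ref.append((yi, self._size_to_block[size], row))
                else:
                    b._y_conv.append((yi, entry))
        self._tracer_templates: dict = {}

    # -- lookup --------------------------------------------------------

    def locate(self, emu: EMU) -> tuple[int, int]:
        """(block position, row) of an unknown EMU in the cascade."""
        for bi, b in enumerate(self.blocks):
            if emu in b.index:
                return bi, b.index[emu]
        raise KeyError(str(emu))

    def _block_of_size(self, size: int) -> int:
        for bi, b in enumerate(self.blocks):
            if b.size == size:
                return bi
        raise KeyError(size)

    # -- simulation ----------------------------------------------------

    def simulate(
        self, v: np.ndarray, tracers: "TracerSpec | list[TracerSpec]"
    ) -> list[dict[EMU, np.ndarray]]:
        """Solve all blocks at flux vector v for one or more tracers.

        Returns one {EMU: MID} dict per tracer.
        """
        single = isinstance(tracers, TracerSpec)
        tr_list = [tracers] if single else list(tracers)
        X, _, _ = self._solve(np.asarray(v, float), tr_list)
        out = []
        for t_i in range(len(tr_list)):
            d: dict[EMU, np.ndarray] = {}
            for bi, b in enumerate(self.blocks):
                for emu, row in b.index.items():
                    d[emu] = X[bi][row, :, t_i]
            out.append(d)
        return out

    def _tracer_mid(self, tracer: TracerSpec, emu: EMU) -> np.ndarray:
        if emu.metabolite == tracer.metabolite:
            return tracer.emu_mid(emu)
        mid = np.zeros(emu.size + 1)  # unlabeled substrate
        mid[0] = 1.0
        return mid

    def _solve(self, v: np.ndarray, tracers: list[TracerSpec], strict: bool = True):
        """Returns (X, LU) lists; X[bi] has shape (n_emus, size+1, T).

        With ``strict=False`` (used by the optimizer, whose line search may
        touch the flux-cone boundary) fluxes are floored at 1e-9 instead of
        raising, which is the smooth limiting behaviour of the balances.
        """
        if not strict:
            v = np.maximum(v, 1e-9)
        T = len(tracers)
        templates = self._templates(tuple(tracers))
        X: list[np.ndarray] = []
        LU = []
        Ys = []
        for bi, b in enumerate(self.blocks):
            n = len(b.emus)
            L = b.size + 1
            A = (b._A_mat @ v).reshape(n, n)
            diag = A.ravel()[:: n + 1]
            if (np.abs(diag) < 1e-12).any():
                bad = [str(b.emus[i]) for i in np.nonzero(np.abs(diag) < 1e-12)[0]]
                raise SingularCascadeError(
                    f"zero total flux through EMU(s) {', '.join(bad)}"
                )
            ny = max(len(b.y_entries), 1)
            Y = templates[bi].copy()
            for yi, sbi, row in b._y_ref:
                Y[yi] = X[sbi][row]
            for yi, entry in b._y_conv:
                for t_i, tr in enumerate(tracers):
                    Y[yi, :, t_i] = self._eval_entry(entry, tr, t_i, X)
            B = (b._B_mat @ v).reshape(n, ny)
            rhs = B @ Y.reshape(ny, L * T)
            lu, piv, info = _lapack.dgetrf(A, overwrite_a=True)
            if info != 0:
                raise SingularCascadeError(
                    f"singular EMU system in size-{b.size} block"
                )
            sol, info = _lapack.dgetrs(lu, piv, rhs)
            if info != 0:
                raise SingularCascadeError(
                    f"singular EMU system in size-{b.size} block"
                )
            X.append(sol.reshape(n, L, T))
            LU.append((lu, piv))
            Ys.append(Y)
        return X, LU, Ys

    def _templates(self, tracers: tuple) -> list[np.ndarray]:
        """Per-block Y arrays with the tracer-constant entries prefilled."""
        key = tracers
        if key not in self._tracer_templates:
            T = len(tracers)
            tpl = []
            for b in self.blocks:
                ny = max(len(b.y_entries), 1)
                Y = np.zeros((ny, b.size + 1, T))
                for yi, emu in b._y_x:
                    for t_i, tr in enumerate(tracers):
                        Y[yi, :, t_i] = self._tracer_mid(tr, emu)
                tpl.append(Y)
            self._tracer_templates[key] = tpl
        return self._tracer_templates[key]

    def _eval_entry(self, entry, tracer, t_i, X) -> np.ndarray:
        vals = []
        for kind, *ref in entry:
            if kind == "x":
                vals.append(self._tracer_mid(tracer, ref[0]))
            else:
                size, row = ref
                bi = self._block_of_size(size)
                vals.append(X[bi][row, :, t_i])
        out = vals[0]
        for m in vals[1:]:
            out = np.convolve(out, m)
        return out

    # -- sensitivities -------------------------------------------------

    def compile_sensitivities(self, K: np.ndarray) -> "SensitivityCascade":
        """Compile analytic d(MID)/du for the parameterization v = K u."""
        return SensitivityCascade(self, K)


def _as_arrays(trip):
    if not trip:
        z = np.zeros(0, dtype=int)
        return z, z, z, np.zeros(0)
    r, c, f, w = zip(*trip)
    return (
        np.array(r, dtype=int),
        np.array(c, dtype=int),
        np.array(f, dtype=int),
        np.array(w, dtype=float),
    )


def _conv_matrix(a: np.ndarray, lb: int) -> np.ndarray:
    """Matrix C with C @ b == convolve(a, b) for b of length lb."""
    la = len(a)
    C = np.zeros((la + lb - 1, lb))
    for j in range(lb):
        C[j : j + la, j] = a
    return C


class SensitivityCascade:
    """Forward sensitivities dX/du for v = K u, reusing block LU factors.

    For each block, dA/du_i and dB/du_i are constant matrices precomputed
    from the assembly triplets and K; per-parameter right-hand sides are
    solved with the block's stored factorization, so one objective-plus-
    gradient evaluation costs a single factorization per block plus p
    back-substitutions.
    """

    def __init__(self, cascade: EMUCascade, K: np.ndarray):
        self.cascade = cascade
        self.K = np.asarray(K, float)
        p = self.K.shape[1]
        self.p = p
        self._dA = []
        self._dB = []
        for b in cascade.blocks:
            n = len(b.emus)
            ny = max(len(b.y_entries), 1)
            dA = np.zeros((p, n, n))
            for r, c, f, w in b.a_trip:
                dA[:, r, c] += w * self.K[f, :]
            dB = np.zeros((p, n, ny))
            for r, c, f, w in b.b_trip:
                dB[:, r, c] += w * self.K[f, :]
            self._dA.append(dA)
            self._dB.append(dB)

    def simulate(self, u: np.ndarray, tracers: list[TracerSpec]):
        """Returns (X, dX) lists per block.

        X[bi]: (n, L, T); dX[bi]: (p, n, L, T), derivatives w.r.t. u.
        """
        casc = self.cascade
        v = np.maximum(self.K @ np.asarray(u, float), 1e-9)
        tr_list = list(tracers)
        T = len(tr_list)
        p = self.p
        X, LU, Ys = casc._solve(v, tr_list, strict=False)
        dX: list[np.ndarray] = []
        for bi, b in enumerate(casc.blocks):
            n = len(b.emus)
            L = b.size + 1
            ny = max(len(b.y_entries), 1)
            Y = Ys[bi]
            dY = np.zeros((p, ny, L, T))
            for yi, sbi, row in b._y_ref:
                dY[:, yi] = dX[sbi][:, row]
            for yi, entry in b._y_conv:
                for t_i, tr in enumerate(tr_list):
                    _, dval = self._entry_with_grad(entry, tr, t_i, X, dX)
                    dY[:, yi, :, t_i] = dval
            B = (b._B_mat @ v).reshape(n, ny)
            # RHS_i = dB_i Y + B dY_i - dA_i X
            Xb = X[bi].reshape(n, L * T)
            rhs = (
                self._dB[bi] @ Y.reshape(ny, L * T)
                + B @ dY.reshape(p, ny, L * T)
                - self._dA[bi] @ Xb
            )
            lu, piv = LU[bi]
            sol, info = _lapack.dgetrs(
                lu, piv, rhs.transpose(1, 0, 2).reshape(n, p * L * T)
            )
            dX.append(sol.reshape(n, p, L, T).transpose(1, 0, 2, 3))
        return X, dX

    def _entry_with_grad(self, entry, tracer, t_i, X, dX):
        casc = self.cascade
        vals, grads = [], []
        for kind, *ref in entry:
            if kind == "x":
                vals.append(casc._tracer_mid(tracer, ref[0]))
                grads.append(None)  # tracer input: constant
            else:
                size, row = ref
                bi = casc._block_of_size(size)
                vals.append(X[bi][row, :, t_i])
                grads.append(dX[bi][:, row, :, t_i])
        out = vals[0]
        dout = grads[0] if grads[0] is not None else np.zeros((self.p, len(vals[0])))
        for m, dm in zip(vals[1:], grads[1:]):
            Cm = _conv_matrix(m, len(out))
            new = Cm @ out
            dnew = dout @ Cm.T
            if dm is not None:
                Co = _conv_matrix(out, len(m))
                dnew = dnew + dm @ Co.T
            out, dout = new, dnew
        return out, dout


def decompose(model: NetworkModel, targets: list[EMU]) -> EMUCascade:
    """Build the EMU cascade reaching backward from `targets`."""
    return EMUCascade(model, targets)


def full_emu(model: NetworkModel, metabolite: str) -> EMU:
    n = model.metabolites[metabolite].n_carbons
    return EMU(metabolite, tuple(range(1, n + 1)))


def measured_cascade(model: NetworkModel) -> EMUCascade:
    """Cascade covering the full EMUs of all measured metabolites."""
    return decompose(model, [full_emu(model, m) for m in model.measured_metabolites])


def simulate_mids(
    cascade: EMUCascade, v: np.ndarray, tracer: TracerSpec
) -> dict[str, np.ndarray]:
    """Steady-state MIDs of the cascade's target metabolites for one tracer."""
    sol = cascade.simulate(v, tracer)[0]
    return {t.metabolite: sol[t] for t in cascade.targets}
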