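"""Atom-mapped metabolic network models and their flux parameterization.

A network model consists of metabolites (with carbon counts and roles),
atom-mapped reactions, the stoichiometric matrix S over *balanced*
metabolites, and a null-space parameterization of the steady-state flux
cone {v : S v = 0, v >= 0}.

The model file dialect is a UTF-8 TSV with columns
``reaction_id  equation  reversible  notes`` plus directive lines:

.. code-block:: text

    #substrate PYR.ext
    #sink CO2
    #measured PYR
    reaction_id	equation	reversible	notes
    PDH	PYR(abc) -> ACCOA(bc) + CO2(a)	0	pyruvate dehydrogenase

Equation grammar: ``coef METAB(letters) [+ ...] -> coef METAB(letters) [+ ...]``
where ``coef`` defaults to 1 and the parenthesized carbon-letter string is
optional (effluxes omit it).  Letters index carbons in written order
(letter 'a' = carbon 1).  Reversible reactions (flag 1) are split into two
irreversible reactions ``ID`` and ``ID_rev`` so the v >= 0 constraint
applies uniformly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "ReactionTerm",
    "Reaction",
    "NetworkModel",
    "FluxParameterization",
    "ModelParseError",
    "parse_model",
    "parse_model_text",
    "write_model",
    "null_space_basis",
    "fluxes_from_free",
]


class ModelParseError(ValueError):
    """Raised when a model file violates the grammar or an invariant."""


@dataclass(frozen=True)
class Metabolite:
    name: str
    n_carbons: int
    role: str = "balanced"  # balanced | substrate | sink
    measured: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("balanced", "substrate", "sink"):
            raise ValueError(f"unknown metabolite role {self.role!r}")


@dataclass(frozen=True)
class ReactionTerm:
    metabolite: str
    coeff: Fraction
    atoms: str | None  # carbon-letter string, None if unmapped


@dataclass(frozen=True)
class Reaction:
    id: str
    reactants: tuple[ReactionTerm, ...]
    products: tuple[ReactionTerm, ...]
    notes: str = ""

    @property
    def is_efflux(self) -> bool:
        return len(self.products) == 0


_TERM_RE = re.compile(
    r"^\s*(?:(?P<coef>\d+(?:\.\d+)?|\d+/\d+)\s+)?"
    r"(?P<met>[A-Za-z_][A-Za-z0-9_.]*)\s*"
    r"(?:\(\s*(?P<atoms>[a-z]+)\s*\))?\s*$"
)


def _parse_side(side: str, rxn_id: str) -> tuple[ReactionTerm, ...]:
    side = side.strip()
    if not side:
        return ()
    terms = []
    for chunk in side.split("+"):
        m = _TERM_RE.match(chunk)
        if m is None:
            raise ModelParseError(f"reaction {rxn_id}: cannot parse term {chunk!r}")
        coef_s = m.group("coef")
        coef = Fraction(coef_s) if coef_s else Fraction(1)
        atoms = m.group("atoms")
        if atoms is not None and len(set(atoms)) != len(atoms):
            raise ModelParseError(
                f"reaction {rxn_id}: repeated carbon letter within one term {chunk!r}"
            )
        terms.append(ReactionTerm(m.group("met"), coef, atoms))
    return tuple(terms)


def _letter_multiset(terms: Sequence[ReactionTerm]) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for t in terms:
        if t.atoms is None:
            continue
        for ch in t.atoms:
            out[ch] = out.get(ch, Fraction(0)) + t.coeff
    return out


def _check_atom_balance(rxn: Reaction) -> None:
    lhs = _letter_multiset(rxn.reactants)
    rhs = _letter_multiset(rxn.products)
    if rxn.is_efflux:
        return  # effluxes leave the labelled system; no product map required
    if lhs != rhs:
        missing = {k: v for k, v in lhs.items() if rhs.get(k) != v}
        extra = {k: v for k, v in rhs.items() if lhs.get(k) != v}
        raise ModelParseError(
            f"reaction {rxn.id}: atom map not conserved "
            f"(reactant letters {dict(sorted(lhs.items()))} vs "
            f"product letters {dict(sorted(rhs.items()))}; "
            f"mismatch on {sorted(set(missing) | set(extra))})"
        )


def _parse_equation(rxn_id: str, eq: str) -> tuple[tuple[ReactionTerm, ...], tuple[ReactionTerm, ...]]:
    if "->" not in eq:
        raise ModelParseError(f"reaction {rxn_id}: missing '->' in equation {eq!r}")
    lhs, rhs = eq.split("->", 1)
    reactants = _parse_side(lhs, rxn_id)
    products = _parse_side(rhs, rxn_id)
    if not reactants:
        raise ModelParseError(f"reaction {rxn_id}: no reactants")
    return reactants, products


def _reverse(rxn: Reaction) -> Reaction:
    return Reaction(rxn.id + "_rev", rxn.products, rxn.reactants, rxn.notes)


class NetworkModel:
    """A validated atom-mapped network with stoichiometry and flux basis."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        name: str = "model",
    ):
        self.name = name
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.name in self.metabolites:
                raise ModelParseError(f"duplicate metabolite {m.name}")
            self.metabolites[m.name] = m
        self.reactions: list[Reaction] = []
        seen = set()
        for r in reactions:
            if r.id in seen:
                raise ModelParseError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            _check_atom_balance(r)
            self.reactions.append(r)
        self._validate_references()
        self.balanced = [m.name for m in self.metabolites.values() if m.role == "balanced"]
        self.measured_metabolites = [
            m.name for m in self.metabolites.values() if m.measured
        ]
        self.S = self._stoichiometric_matrix()
        self._param: FluxParameterization | None = None

    # -- construction -------------------------------------------------

    def _validate_references(self) -> None:
        for r in self.reactions:
            for t in r.reactants + r.products:
                met = self.metabolites.get(t.metabolite)
                if met is None:
                    raise ModelParseError(
                        f"reaction {r.id}: unknown metabolite {t.metabolite}"
                    )
                if t.atoms is not None and len(t.atoms) != met.n_carbons:
                    raise ModelParseError(
                        f"reaction {r.id}: atom map {t.atoms!r} has "
                        f"{len(t.atoms)} letters but {met.name} has "
                        f"{met.n_carbons} carbons"
                    )

    def _stoichiometric_matrix(self) -> np.ndarray:
        idx = {m: i for i, m in enumerate(self.balanced)}
        S = np.zeros((len(self.balanced), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for t in r.reactants:
                if t.metabolite in idx:
                    S[idx[t.metabolite], j] -= float(t.coeff)
            for t in r.products:
                if t.metabolite in idx:
                    S[idx[t.metabolite], j] += float(t.coeff)
        return S

    # -- convenience ---------------------------------------------------

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction_index(self, rxn_id: str) -> int:
        for i, r in enumerate(self.reactions):
            if r.id == rxn_id:
                return i
        raise KeyError(rxn_id)

    def producers(self, metabolite: str) -> list[tuple[int, ReactionTerm]]:
        """(reaction index, product term) pairs producing `metabolite`."""
        out = []
        for j, r in enumerate(self.reactions):
            for t in r.products:
                if t.metabolite == metabolite:
                    out.append((j, t))
        return out

    def consumption(self, metabolite: str) -> list[tuple[int, Fraction]]:
        """(reaction index, coefficient) pairs consuming `metabolite`."""
        out = []
        for j, r in enumerate(self.reactions):
            c = sum((t.coeff for t in r.reactants if t.metabolite == metabolite),
                    Fraction(0))
            if c:
                out.append((j, c))
        return out

    def parameterization(
        self, lb: float = 0.0, ub: float = 100.0, fixed_flux: str | None = None
    ) -> "FluxParameterization":
        """Null-space flux parameterization (cached for default arguments)."""
        if self._param is not None and fixed_flux is None and lb == 0.0 and ub == 100.0:
            return self._param
        p = FluxParameterization.from_model(self, lb=lb, ub=ub, fixed_flux=fixed_flux)
        if fixed_flux is None and lb == 0.0 and ub == 100.0:
            self._param = p
        return p

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )

    def __repr__(self) -> str:
        return (
            f"NetworkModel({self.name!r}, {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions)"
        )


def null_space_basis(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis K of ker(S) with S @ K = 0 to within `tol`.

    Raises if the network is fully determined (nullity zero).
    """
    from scipy.linalg import null_space

    S = np.asarray(S, dtype=float)
    if S.ndim == 1:
        S = S[None, :]
    K = null_space(S)
    if K.shape[1] == 0:
        raise ValueError("network fully determined; no free fluxes")
    resid = np.abs(S @ K).max()
    if resid > tol:  # pragma: no cover - numerical safety net
        raise ValueError(f"null-space residual {resid:.2e} exceeds {tol}")
    return K


def _rref_basis(S: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Rational RREF null-space basis of S.

    Returns (K, free_cols): v = K @ u with u = v[free_cols], so the free
    fluxes are actual network fluxes and u >= 0 is a natural bound.
    """
    import sympy

    M = sympy.Matrix([[sympy.nsimplify(x, rational=True) for x in row] for row in S])
    R, pivots = M.rref()
    n = S.shape[1]
    free_cols = [j for j in range(n) if j not in pivots]
    if not free_cols:
        raise ValueError("network fully determined; no free fluxes")
    K = np.zeros((n, len(free_cols)))
    for uj, j in enumerate(free_cols):
        K[j, uj] = 1.0
    for pi, pj in enumerate(pivots):
        for uj, j in enumerate(free_cols):
            K[pj, uj] = -float(R[pi, j])
    return K, free_cols


@dataclass
class FluxParameterization:
    """v = K u over the steady-state flux cone.

    K is a rational-echelon null-space basis whose free coordinates are a
    subset of the network fluxes themselves, so lb <= u <= ub are natural
    box bounds and feasibility is K u >= 0 (which subsumes u >= 0 because
    the free rows of K are identity rows).  An optional normalization
    fixes one flux to 1 via the equality row ``K[fixed_index] @ u = 1``.
    """

    model: NetworkModel
    K: np.ndarray
    free_indices: list[int]
    lb: float = 0.0
    ub: float = 100.0
    fixed_index: int | None = None  # row of v (reaction index) pinned to 1

    @classmethod
    def from_model(
        cls,
        model: NetworkModel,
        lb: float = 0.0,
        ub: float = 100.0,
        fixed_flux: str | None = None,
    ) -> "FluxParameterization":
        K, free_cols = _rref_basis(model.S)
        resid = np.abs(model.S @ K).max()
        if resid > 1e-10:  # pragma: no cover
            raise ValueError(f"null-space residual {resid:.2e}")
        fixed = model.reaction_index(fixed_flux) if fixed_flux else None
        return cls(model, K, free_cols, lb=lb, ub=ub, fixed_index=fixed)

    @property
    def nullity(self) -> int:
        return self.K.shape[1]

    @property
    def n_free_parameters(self) -> int:
        """Effective free parameter count (normalization removes one)."""
        return self.nullity - (0 if self.fixed_index is None else 1)

    def fluxes(self, u: np.ndarray) -> np.ndarray:
        return fluxes_from_free(self, u)

    def free_from_fluxes(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape != (self.K.shape[0],):
            raise ValueError("flux vector has wrong length")
        return v[self.free_indices]

    def is_feasible(self, u: np.ndarray, tol: float = 1e-9) -> bool:
        v = self.fluxes(u)
        u = np.asarray(u, dtype=float)
        return bool(
            (v >= -tol).all() and (u >= self.lb - tol).all() and (u <= self.ub + tol).all()
        )


def fluxes_from_free(param: FluxParameterization, u: np.ndarray) -> np.ndarray:
    """Full flux vector v = K u.  Raises on dimension mismatch."""
    u = np.asarray(u, dtype=float)
    if u.shape != (param.K.shape[1],):
        raise ValueError(
            f"free-flux vector has length {u.shape}, expected {param.K.shape[1]}"
        )
    return param.K @ u


# ----------------------------------------------------------------------
# File I/O


def parse_model_text(text: str, name: str = "model") -> NetworkModel:
    substrates: list[str] = []
    sinks: list[str] = []
    measured: list[str] = []
    rows: list[tuple[str, str, str, str]] = []
    sep = "\t" if "\t" in text else ","
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split()
            if not parts:
                continue
            kind = parts[0].lower()
            if kind == "substrate":
                substrates.extend(parts[1:])
            elif kind == "sink":
                sinks.extend(parts[1:])
            elif kind == "measured":
                measured.extend(parts[1:])
            # other comment lines ignored
            continue
        fields = [f.strip() for f in line.split(sep)]
        if fields[0].lower() == "reaction_id":
            continue
        if len(fields) < 2:
            raise ModelParseError(f"line {lineno}: expected at least 2 columns")
        rid, eq = fields[0], fields[1]
        rev = fields[2] if len(fields) > 2 and fields[2] else "0"
        notes = fields[3] if len(fields) > 3 else ""
        rows.append((rid, eq, rev, notes))

    reactions: list[Reaction] = []
    for rid, eq, rev, notes in rows:
        reactants, products = _parse_equation(rid, eq)
        rxn = Reaction(rid, reactants, products, notes)
        reactions.append(rxn)
        if rev not in ("0", "1"):
            raise ModelParseError(f"reaction {rid}: reversible flag must be 0 or 1")
        if rev == "1":
            reactions.append(_reverse(rxn))

    # infer carbon counts from atom maps
    n_carbons: dict[str, int] = {}
    mentioned: list[str] = []
    for r in reactions:
        for t in r.reactants + r.products:
            if t.metabolite not in mentioned:
                mentioned.append(t.metabolite)
            if t.atoms is not None:
                prev = n_carbons.setdefault(t.metabolite, len(t.atoms))
                if prev != len(t.atoms):
                    raise ModelParseError(
                        f"inconsistent carbon count for {t.metabolite}: "
                        f"{prev} vs {len(t.atoms)} in reaction {r.id}"
                    )
    metabolites = []
    for name_ in mentioned:
        role = (
            "substrate" if name_ in substrates
            else "sink" if name_ in sinks
            else "balanced"
        )
        metabolites.append(
            Metabolite(name_, n_carbons.get(name_, 0), role, name_ in measured)
        )
    for m in measured:
        if m not in mentioned:
            raise ModelParseError(f"measured metabolite {m} not in any reaction")
    return NetworkModel(metabolites, reactions, name=name)


def parse_model(model_file: str | Path) -> NetworkModel:
    """Parse a model file in the TSV dialect; see module docstring."""
    path = Path(model_file)
    return parse_model_text(path.read_text(), name=path.stem)


def _format_term(t: ReactionTerm) -> str:
    coef = "" if t.coeff == 1 else f"{t.coeff} "
    atoms = f"({t.atoms})" if t.atoms is not None else ""
    return f"{coef}{t.metabolite}{atoms}"


def write_model(model: NetworkModel, path: str | Path | None = None) -> str:
    """Serialize a model to the same TSV dialect the parser accepts.

    Reversible pairs are written back as the two explicit irreversible
    reactions, so a write/parse round trip is the identity.
    """
    lines = []
    for role, kw in (("substrate", "#substrate"), ("sink", "#sink")):
        names = [m.name for m in model.metabolites.values() if m.role == role]
        if names:
            lines.append(f"{kw} " + " ".join(names))
    meas = [m.name for m in model.metabolites.values() if m.measured]
    if meas:
        lines.append("#measured " + " ".join(meas))
    lines.append("reaction_id\tequation\treversible\tnotes")
    for r in model.reactions:
        lhs = " + ".join(_format_term(t) for t in r.reactants)
        rhs = " + ".join(_format_term(t) for t in r.products)
        lines.append(f"{r.id}\t{lhs} -> {rhs}\t0\t{r.notes}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
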