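"""Model representation and stoichiometry storage.

A model is a well-mixed chemical system: a list of species with integer
molecule counts and a list of irreversible mass-action reaction channels of
order 0, 1, or 2.  The net-change (stoichiometry) matrix is held either dense
(species x reactions) or in compressed row storage (CRS) oriented
reaction-major, so that firing reaction ``j`` touches only the few species in
CRS row ``j`` instead of scanning a full matrix column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ReactionSpec",
    "ModelSpec",
    "DenseStoichiometry",
    "CRSStoichiometry",
    "ModelValidationError",
    "validate_model",
    "require_valid",
    "dense_from_model",
    "crs_compress",
    "crs_decompress",
    "crs_from_model",
    "footprint_dense",
    "footprint_crs",
    "footprint_report",
]


class ModelValidationError(ValueError):
    """Raised when an operation requires a valid model but got violations."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid model: " + "; ".join(self.violations))


@dataclass(frozen=True)
class ReactionSpec:
    """One irreversible mass-action reaction channel.

    Parameters
    ----------
    id : str
        Label for error messages and SBML round-trips.
    rate_constant : float
        Stochastic rate constant ``c`` (per-event rate on the count scale;
        units 1/time for order <= 1, 1/(time*count) for order 2).
    reactants, products : sequence of (species_index, coefficient)
        Integer stoichiometric coefficients >= 1; a species index appears at
        most once per side.  Reaction order is the sum of reactant
        coefficients and must be 0, 1, or 2.
    """

    id: str
    rate_constant: float
    reactants: tuple[tuple[int, int], ...] = ()
    products: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple((int(s), int(k)) for s, k in self.reactants))
        object.__setattr__(self, "products", tuple((int(s), int(k)) for s, k in self.products))

    @property
    def order(self) -> int:
        return sum(k for _, k in self.reactants)


@dataclass(frozen=True)
class ModelSpec:
    """Species, integer initial counts, and the reaction list."""

    species: tuple[str, ...]
    initial_counts: tuple[int, ...]
    reactions: tuple[ReactionSpec, ...]

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(str(s) for s in self.species))
        object.__setattr__(self, "initial_counts", tuple(int(x) for x in self.initial_counts))
        object.__setattr__(self, "reactions", tuple(self.reactions))

    @property
    def m_species(self) -> int:
        return len(self.species)

    @property
    def n(self) -> int:
        """Number of reactions."""
        return len(self.reactions)


@dataclass(frozen=True)
class DenseStoichiometry:
    """Net-change matrix, species rows x reaction columns."""

    matrix: np.ndarray  # signed integers, shape (m_species, n)

    def __post_init__(self):
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=np.int64))


@dataclass(frozen=True)
class CRSStoichiometry:
    """Compressed row storage of the net-change matrix, reaction-major.

    One row per reaction: ``species_idx[row_ptr[j]:row_ptr[j+1]]`` are the
    species whose counts change when reaction ``j`` fires, with signed
    ``net_change`` entries.  Only nonzero net changes are stored, so a
    catalyst (same species, same coefficient on both sides) does not appear.
    """

    row_ptr: np.ndarray
    species_idx: np.ndarray
    net_change: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "row_ptr", np.asarray(self.row_ptr, dtype=np.int64))
        object.__setattr__(self, "species_idx", np.asarray(self.species_idx, dtype=np.int64))
        object.__setattr__(self, "net_change", np.asarray(self.net_change, dtype=np.int64))

    @property
    def n(self) -> int:
        return len(self.row_ptr) - 1

    @property
    def alpha(self) -> int:
        """Total number of stored (nonzero) entries."""
        return int(self.row_ptr[-1])

    def row(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.row_ptr[j], self.row_ptr[j + 1]
        return self.species_idx[lo:hi], self.net_change[lo:hi]


def validate_model(model: ModelSpec) -> list[str]:
    """Return a list of violation messages; an empty list means valid.

    Checks: reaction order in {0, 1, 2}; nonnegative rate constants and
    initial counts; species indices in range; no species repeated on one
    side of a reaction; counts match species list length; at least one
    reaction.
    """
    v: list[str] = []
    m = model.m_species
    if len(model.initial_counts) != m:
        v.append(
            f"initial_counts has {len(model.initial_counts)} entries for {m} species"
        )
    for i, x in enumerate(model.initial_counts):
        if x < 0:
            v.append(f"species {model.species[i]!r}: negative initial count {x}")
    if model.n < 1:
        v.append("model has no reactions")
    for r in model.reactions:
        if r.order > 2:
            v.append(f"reaction {r.id!r}: order {r.order} > 2")
        if r.rate_constant < 0:
            v.append(f"reaction {r.id!r}: negative rate constant {r.rate_constant}")
        for side_name, side in (("reactant", r.reactants), ("product", r.products)):
            seen = set()
            for s, k in side:
                if not (0 <= s < m):
                    v.append(f"reaction {r.id!r}: {side_name} species index {s} out of range")
                if s in seen:
                    v.append(f"reaction {r.id!r}: species index {s} repeated as {side_name}")
                seen.add(s)
                if k < 1:
                    v.append(f"reaction {r.id!r}: {side_name} coefficient {k} < 1")
    return v


def require_valid(model: ModelSpec) -> None:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)


def dense_from_model(model: ModelSpec) -> DenseStoichiometry:
    """Build the dense net-change matrix (products minus reactants)."""
    require_valid(model)
    mat = np.zeros((model.m_species, model.n), dtype=np.int64)
    for j, r in enumerate(model.reactions):
        for s, k in r.reactants:
            mat[s, j] -= k
        for s, k in r.products:
            mat[s, j] += k
    return DenseStoichiometry(mat)


def crs_compress(dense: DenseStoichiometry) -> CRSStoichiometry:
    """Compress the dense matrix to reaction-major CRS.

    Rows of the CRS are reactions (columns of the dense matrix), because the
    structure exists to serve the firing update: one row lookup per fired
    reaction, no matrix scan.
    """
    csr = sp.csr_matrix(dense.matrix.T)
    csr.eliminate_zeros()
    csr.sort_indices()
    return CRSStoichiometry(
        row_ptr=csr.indptr.astype(np.int64),
        species_idx=csr.indices.astype(np.int64),
        net_change=csr.data.astype(np.int64),
    )


def crs_decompress(crs: CRSStoichiometry, m_species: int) -> DenseStoichiometry:
    """Exact inverse of :func:`crs_compress`."""
    if crs.alpha and crs.species_idx.max() >= m_species:
        raise ValueError(
            f"CRS species index {int(crs.species_idx.max())} out of range for m_species={m_species}"
        )
    n = crs.n
    csr = sp.csr_matrix(
        (crs.net_change, crs.species_idx, crs.row_ptr), shape=(n, m_species)
    )
    return DenseStoichiometry(csr.toarray().T)


def crs_from_model(model: ModelSpec) -> CRSStoichiometry:
    return crs_compress(dense_from_model(model))


def footprint_dense(m_species: int, n: int) -> int:
    """Element count of the dense net-change matrix: m x r."""
    return int(m_species) * int(n)


def footprint_crs(n: int, alpha: int) -> int:
    """Element count of the CRS structure: r + 2*alpha.

    The r row-pointer entries plus, per stored nonzero, one species index and
    one net change.  When alpha = m_bar * r (m_bar species touched per
    reaction on average) this equals (2*m_bar + 1) * r.
    """
    return int(n) + 2 * int(alpha)


_ELEMENT_BYTES = {"int8": 1, "int16": 2, "int32": 4, "int64": 8}


def footprint_report(model: ModelSpec, element_width: str = "int32") -> dict:
    """Structured report: validation result plus dense/CRS footprints.

    Footprints are abstract element counts; byte figures assume the declared
    integer width for every stored element.
    """
    violations = validate_model(model)
    dense = dense_from_model(model) if not violations else None
    out: dict = {
        "species": model.m_species,
        "reactions": model.n,
        "valid": not violations,
        "violations": violations,
    }
    if dense is not None:
        crs = crs_compress(dense)
        width = _ELEMENT_BYTES[element_width]
        out.update(
            {
                "alpha": crs.alpha,
                "footprint_dense_elements": footprint_dense(model.m_species, model.n),
                "footprint_crs_elements": footprint_crs(model.n, crs.alpha),
                "element_width": element_width,
                "footprint_dense_bytes": footprint_dense(model.m_species, model.n) * width,
                "footprint_crs_bytes": footprint_crs(model.n, crs.alpha) * width,
            }
        )
    return out
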