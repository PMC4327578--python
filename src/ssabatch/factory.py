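"""Benchmark model families, built programmatically at any scale.

Two families: the 3-species / 4-reaction decay-dimerization system (S1 decay,
reversible dimerization of S1 into S2 written as two irreversible channels,
and conversion of S2 to S3), and batteries of k independent single-gene
production-reduction units (G -> G + P, P -> 0), an immigration-death process
whose stationary P distribution is Poisson(c5*G/c6).
"""

from __future__ import annotations

from .model import ModelSpec, ReactionSpec

__all__ = ["decay_dimerization", "gene_battery"]

DECAY_DIMER_RATES = (1.0, 0.002, 0.5, 0.04)
DECAY_DIMER_INITIAL = (10_000, 0, 0)
DECAY_DIMER_STEPS = 11_000  # benchmark step budget


def decay_dimerization(
    c: tuple[float, float, float, float] = DECAY_DIMER_RATES,
    initial: tuple[int, int, int] = DECAY_DIMER_INITIAL,
) -> ModelSpec:
    """Decay-dimerization benchmark: S1->0, S1+S1->S2, S2->S1+S1, S2->S3.

    Defaults are the standard benchmark conditions: c = (1.0, 0.002, 0.5,
    0.04) and initial counts (10000, 0, 0).
    """
    c1, c2, c3, c4 = c
    return ModelSpec(
        species=("S1", "S2", "S3"),
        initial_counts=initial,
        reactions=(
            ReactionSpec("r1", c1, reactants=((0, 1),), products=()),
            ReactionSpec("r2", c2, reactants=((0, 2),), products=((1, 1),)),
            ReactionSpec("r3", c3, reactants=((1, 1),), products=((0, 2),)),
            ReactionSpec("r4", c4, reactants=((1, 1),), products=((2, 1),)),
        ),
    )


def gene_battery(
    k: int,
    c5: float = 10.0,
    c6: float = 1.0,
    g0: int = 1,
    p0: int = 0,
) -> ModelSpec:
    """Battery of k independent single-gene production-reduction units.

    Unit i contributes species Gi, Pi and reactions Gi -> Gi + Pi (rate c5,
    catalytic: Gi is a reactant but its net change is zero) and Pi -> 0
    (rate c6); 2k species and 2k reactions in total, block-diagonal
    stoichiometry.  Defaults c5=10, c6=1, g0=1, p0=0 put the stationary mean
    and variance of each Pi at c5*g0/c6 = 10 (Poisson).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    species: list[str] = []
    counts: list[int] = []
    reactions: list[ReactionSpec] = []
    for i in range(1, k + 1):
        gi, pi = len(species), len(species) + 1
        species += [f"G{i}", f"P{i}"]
        counts += [g0, p0]
        reactions.append(
            ReactionSpec(
                f"produce{i}", c5, reactants=((gi, 1),), products=((gi, 1), (pi, 1))
            )
        )
        reactions.append(ReactionSpec(f"degrade{i}", c6, reactants=((pi, 1),), products=()))
    return ModelSpec(tuple(species), tuple(counts), tuple(reactions))
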