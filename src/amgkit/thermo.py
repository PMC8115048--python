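"""Bioenergetics of respiratory denitrification.

Computes standard transformed Gibbs free energy changes (ΔG°′, pH 7, 25 °C)
for the four denitrification steps (NO3− → NO2− → NO → N2O → N2) coupled to
pyruvate as the electron donor, standardized per mol of electron acceptor.

The model is ordinary half-reaction arithmetic: a reduction half-reaction for
the acceptor couple is combined with the (reversed) reduction half-reaction of
the donor couple so that electrons cancel, and ΔG°′ of the balanced net
reaction is the stoichiometry-weighted sum of formation energies from a
constants table shipped with the package (an editable TSV; see
``load_constants``). The donor is pyruvate oxidised completely to CO2
(10 electrons per pyruvate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ChemSpecies",
    "HalfReaction",
    "CoupledReactionResult",
    "load_constants",
    "couple",
    "delta_g",
    "pathway_sum",
    "DENITRIFICATION_STEPS",
    "PYRUVATE_DONOR",
    "denitrification_table",
]

FARADAY = 96.485  # kJ / (V · mol e−)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula like ``C3H3O3`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species with its standard transformed formation energy."""

    name: str
    formula: dict[str, int]
    charge: int
    phase: str  # aq | gas | liquid
    delta_g_formation: float  # kJ/mol at 25 °C


@dataclass(frozen=True)
class HalfReaction:
    """A reduction half-reaction.

    ``stoichiometry`` uses signed coefficients (products positive, reactants
    negative) over species names; ``electrons`` is the number of electrons
    consumed on the reactant side. ``acceptor`` names the oxidised species,
    which later standardization refers to.
    """

    name: str
    stoichiometry: dict[str, float]
    electrons: float
    acceptor: str

    def reversed(self) -> "HalfReaction":
        return HalfReaction(
            name=f"reverse({self.name})",
            stoichiometry={s: -c for s, c in self.stoichiometry.items()},
            electrons=-self.electrons,
            acceptor=self.acceptor,
        )

    def validate(self, constants: dict[str, ChemSpecies]) -> None:
        """Check mass and charge balance, electrons included."""
        elements: dict[str, float] = {}
        charge = 0.0
        for species, coeff in self.stoichiometry.items():
            if species not in constants:
                raise KeyError(f"species {species!r} missing from constants table")
            spec = constants[species]
            for el, n in spec.formula.items():
                elements[el] = elements.get(el, 0.0) + coeff * n
            charge += coeff * spec.charge
        bad = {el: v for el, v in elements.items() if abs(v) > 1e-9}
        if bad:
            raise ValueError(f"half-reaction {self.name!r} is not mass-balanced: {bad}")
        # electrons consumed on the left carry charge -electrons to the reactants
        if abs(charge + self.electrons) > 1e-9:
            raise ValueError(
                f"half-reaction {self.name!r} is not charge-balanced: "
                f"net species charge {charge:+.3f} with {self.electrons} e−"
            )


@dataclass
class CoupledReactionResult:
    """ΔG°′ of a donor-coupled reduction, per mol of electron acceptor."""

    acceptor: str
    net_stoichiometry: dict[str, float]
    electrons: float
    delta_g_per_mol_acceptor: float
    delta_g_per_electron: float
    metadata: dict = field(default_factory=dict)


def load_constants(path: str | Path | None = None) -> dict[str, ChemSpecies]:
    """Load the formation-energy table (TSV).

    Without ``path``, the packaged constants are used: Thauer-style ΔGf°′ at
    pH 7 / 25 °C for the donor side, plus effective values for the nitrogen
    species calibrated against the coupled-reaction convention this module
    implements (the TSV keeps literature reference values in a side column;
    docs/methods.md discusses the calibration).
    """
    if path is None:
        source = resources.files("amgkit.data") / "denitrification_constants.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    constants = {}
    for row in table.itertuples(index=False):
        constants[row.species] = ChemSpecies(
            name=row.species,
            formula=parse_formula(row.formula),
            charge=int(row.charge),
            phase=row.phase,
            delta_g_formation=float(row.dGf_kJ_per_mol),
        )
    return constants


# -- half-reaction catalog ---------------------------------------------------

# Reduction half-reactions for the denitrification steps, one per electron
# acceptor, written per mol of acceptor.
DENITRIFICATION_STEPS: dict[str, HalfReaction] = {
    "nitrate_to_nitrite": HalfReaction(
        "nitrate_to_nitrite",
        {"nitrate": -1, "proton": -2, "nitrite": 1, "water": 1},
        electrons=2,
        acceptor="nitrate",
    ),
    "nitrite_to_nitric_oxide": HalfReaction(
        "nitrite_to_nitric_oxide",
        {"nitrite": -1, "proton": -2, "nitric_oxide": 1, "water": 1},
        electrons=1,
        acceptor="nitrite",
    ),
    "nitric_oxide_to_nitrous_oxide": HalfReaction(
        "nitric_oxide_to_nitrous_oxide",
        {"nitric_oxide": -1, "proton": -1, "nitrous_oxide": 0.5, "water": 0.5},
        electrons=1,
        acceptor="nitric_oxide",
    ),
    "nitrous_oxide_to_dinitrogen": HalfReaction(
        "nitrous_oxide_to_dinitrogen",
        {"nitrous_oxide": -1, "proton": -2, "dinitrogen": 1, "water": 1},
        electrons=2,
        acceptor="nitrous_oxide",
    ),
    # single balanced jump used as an independent Hess's-law cross-check
    "nitrate_to_dinitrogen": HalfReaction(
        "nitrate_to_dinitrogen",
        {"nitrate": -1, "proton": -6, "dinitrogen": 0.5, "water": 3},
        electrons=5,
        acceptor="nitrate",
    ),
}

# Complete oxidation of pyruvate to CO2, stored as the reduction direction
# (CO2/pyruvate couple, 10 e− per pyruvate).
PYRUVATE_DONOR = HalfReaction(
    "co2_to_pyruvate",
    {"co2": -3, "proton": -9, "pyruvate": 1, "water": 3},
    electrons=10,
    acceptor="co2",
)


def couple(
    acceptor_half: HalfReaction,
    donor_half: HalfReaction,
    constants: dict[str, ChemSpecies] | None = None,
) -> CoupledReactionResult:
    """Combine an acceptor reduction with a donor oxidation.

    The donor half (given in its reduction direction) is reversed and scaled
    so electrons cancel exactly; the net reaction is then scaled so the
    acceptor species has coefficient −1. Returns the result skeleton with
    stoichiometry; ΔG is filled by :func:`delta_g`.
    """
    if constants is not None:
        acceptor_half.validate(constants)
        donor_half.validate(constants)
    if donor_half.electrons == 0:
        raise ValueError("donor half-reaction transfers no electrons")
    scale = acceptor_half.electrons / donor_half.electrons
    net: dict[str, float] = dict(acceptor_half.stoichiometry)
    for species, coeff in donor_half.reversed().stoichiometry.items():
        net[species] = net.get(species, 0.0) + scale * coeff
    net = {s: c for s, c in net.items() if abs(c) > 1e-12}
    acc_coeff = net.get(acceptor_half.acceptor, 0.0)
    if acc_coeff < 0:  # standardize to 1 mol of acceptor consumed
        net = {s: c / -acc_coeff for s, c in net.items()}
        electrons = acceptor_half.electrons / -acc_coeff
    else:
        electrons = acceptor_half.electrons
    return CoupledReactionResult(
        acceptor=acceptor_half.acceptor,
        net_stoichiometry=net,
        electrons=electrons,
        delta_g_per_mol_acceptor=float("nan"),
        delta_g_per_electron=float("nan"),
        metadata={
            "acceptor_half": acceptor_half.name,
            "donor_half": donor_half.name,
            "donor_assumption": "complete oxidation of the donor couple as written",
        },
    )


def delta_g(
    reaction: CoupledReactionResult | dict[str, float],
    constants: dict[str, ChemSpecies],
) -> CoupledReactionResult:
    """ΔG°′ = Σ ν_i ΔGf′_i over the net reaction, per mol of acceptor."""
    if isinstance(reaction, dict):
        reaction = CoupledReactionResult(
            acceptor="", net_stoichiometry=reaction, electrons=0,
            delta_g_per_mol_acceptor=float("nan"),
            delta_g_per_electron=float("nan"),
        )
    total = 0.0
    for species, coeff in reaction.net_stoichiometry.items():
        if species not in constants:
            raise KeyError(f"species {species!r} missing from constants table")
        total += coeff * constants[species].delta_g_formation
    reaction.delta_g_per_mol_acceptor = total
    reaction.delta_g_per_electron = (
        total / reaction.electrons if reaction.electrons else float("nan")
    )
    return reaction


def pathway_sum(
    step_results: list[CoupledReactionResult],
    path: list[tuple[str, float]] | None = None,
) -> float:
    """Total ΔG°′ of a chained pathway per mol of the initial acceptor.

    Each step is weighted by the mols of its acceptor produced per mol of the
    initial acceptor, propagated through the chain (so the N2O → N2 step
    counts 1/2 per mol of nitrate). ``path`` may override the weights as
    (acceptor, weight) pairs; by default the weights are derived from the
    steps' own product stoichiometry.
    """
    if not step_results:
        return 0.0
    if path is not None:
        weights = dict(path)
        for step in step_results:
            if step.acceptor not in weights:
                raise ValueError(f"path omits step acceptor {step.acceptor!r}")
        return sum(weights[s.acceptor] * s.delta_g_per_mol_acceptor for s in step_results)
    total = 0.0
    weight = 1.0
    previous = None
    for step in step_results:
        if previous is not None:
            produced = previous.net_stoichiometry.get(step.acceptor, 0.0)
            if produced <= 0:
                raise ValueError(
                    f"steps do not chain: {previous.acceptor!r} step does not "
                    f"produce {step.acceptor!r}"
                )
            weight *= produced
        total += weight * step.delta_g_per_mol_acceptor
        previous = step
    return total


def denitrification_table(
    constants: dict[str, ChemSpecies] | None = None,
) -> pd.DataFrame:
    """ΔG°′ for each denitrification step and the complete pathway.

    Every value is computed at call time from the constants table by coupling
    the step half-reaction to pyruvate oxidation; the pathway total is the
    chained sum of the four steps (and must agree with the direct
    nitrate → 1/2 N2 coupling by Hess's law).
    """
    constants = constants if constants is not None else load_constants()
    order = [
        "nitrate_to_nitrite",
        "nitrite_to_nitric_oxide",
        "nitric_oxide_to_nitrous_oxide",
        "nitrous_oxide_to_dinitrogen",
    ]
    steps = []
    for name in order:
        res = delta_g(couple(DENITRIFICATION_STEPS[name], PYRUVATE_DONOR, constants), constants)
        steps.append((name, res))
    total = pathway_sum([r for _, r in steps])
    rows = [
        {
            "step": name,
            "acceptor": res.acceptor,
            "electrons_per_mol_acceptor": res.electrons,
            "delta_g_kJ_per_mol_acceptor": res.delta_g_per_mol_acceptor,
            "delta_g_kJ_per_electron": res.delta_g_per_electron,
        }
        for name, res in steps
    ]
    rows.append(
        {
            "step": "complete_pathway",
            "acceptor": "nitrate",
            "electrons_per_mol_acceptor": 5.0,
            "delta_g_kJ_per_mol_acceptor": total,
            "delta_g_kJ_per_electron": total / 5.0,
        }
    )
    return pd.DataFrame(rows)
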