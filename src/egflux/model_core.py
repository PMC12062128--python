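"""Reduced core stoichiometric model of *Rhodotorula toruloides* central
carbon metabolism with a curated ethylene-glycol (EG) oxidation pathway.

The network covers glucose uptake and glycolysis, the oxidative and
(non-oxidative, lumped) pentose phosphate pathway, the xylose
reductase / xylitol dehydrogenase / xylulokinase route with its
D-arabitol side reactions, a compartmented TCA cycle, the peroxisomal
glyoxylate shunt (isocitrate lyase, glyoxylate export to the cytosol),
cytosolic and mitochondrial glyoxylate reductase, lumped oxidative
phosphorylation, and a biomass reaction with explicit ATP and NADPH
demands.  On top of that sits the curated EG pathway: extracellular EG,
cytosolic transport, and a two-step oxidation
EG -> glycolaldehyde (GAH) -> glycolate (GA), each step available in an
NAD- and/or NADP-dependent flavor so that flux analysis can choose which
cofactor the cell regenerates.

All metabolite formulas follow the charged-species convention of the
BiGG database, which makes every internal reaction balance exactly for
C, H, O and N (P and S balance as well but are not enforced).  Exchange
reactions and the biomass drain are exempt from elemental balancing;
biomass is instead checked for carbon consistency against a configurable
elemental composition (default CH1.8O0.5N0.2 per Cmol, the generic
yeast assumption).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ATOMIC_MASSES",
    "BIOMASS_COMPOSITION",
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "ModelError",
    "parse_formula",
    "formula_weight",
    "cmol_mass",
    "build_core_model",
    "check_mass_balance",
    "biomass_carbon_imbalance",
    "read_model",
    "write_model",
    "MODEL_SCHEMA_VERSION",
]

MODEL_SCHEMA_VERSION = "1.0"

COMPARTMENTS = {"e": "extracellular", "c": "cytosol",
                "m": "mitochondrion", "p": "peroxisome"}

ELEMENTS = ("C", "H", "O", "N", "P", "S")
BALANCED_ELEMENTS = ("C", "H", "O", "N")

ATOMIC_MASSES = {
    "C": 12.011, "H": 1.008, "O": 15.999,
    "N": 14.007, "P": 30.974, "S": 32.06,
}

#: generic yeast biomass elemental composition, atoms per Cmol
BIOMASS_COMPOSITION = {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelError(ValueError):
    """Raised for structurally invalid models or malformed model files."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-style formula string (e.g. ``C6H12O6``) into an
    element -> count map restricted to C,H,O,N,P,S."""
    counts: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ModelError(f"cannot parse formula {formula!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in ELEMENTS:
            raise ModelError(f"unsupported element {el!r} in {formula!r}")
        n = float(num) if num else 1.0
        counts[el] = counts.get(el, 0.0) + n
    if pos != len(formula):
        raise ModelError(f"cannot parse formula {formula!r}")
    return counts


def formula_weight(formula: Mapping[str, float]) -> float:
    """Molar mass (g/mol) of an element->count map."""
    return sum(ATOMIC_MASSES[el] * n for el, n in formula.items())


def cmol_mass(composition: Mapping[str, float]) -> float:
    """Gram per Cmol of a biomass composition normalised to one carbon."""
    c = composition.get("C", 0.0)
    if c <= 0:
        raise ModelError("biomass composition must contain carbon")
    return formula_weight(composition) / c


@dataclass
class Metabolite:
    """A chemical species located in one compartment."""

    id: str
    name: str
    compartment: str
    formula: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelError(
                f"metabolite {self.id!r}: unknown compartment "
                f"{self.compartment!r} (allowed: {sorted(COMPARTMENTS)})")
        for el, n in self.formula.items():
            if el not in ELEMENTS:
                raise ModelError(f"metabolite {self.id!r}: element {el!r}")
            if n < 0:
                raise ModelError(f"metabolite {self.id!r}: negative count")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds (mmol/gCDW/h).

    ``cofactor`` tags redox reactions by the pyridine nucleotide they
    use (``NAD``, ``NADP``) and is ``none`` otherwise; it is metadata
    for reporting and route accounting, not part of the stoichiometry.
    """

    id: str
    name: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    cofactor: str = "none"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(f"reaction {self.id!r}: lower bound exceeds upper")
        if not any(c != 0 for c in self.stoichiometry.values()):
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if self.cofactor not in ("NAD", "NADP", "none"):
            raise ModelError(f"reaction {self.id!r}: cofactor {self.cofactor!r}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class StoichiometricModel:
    """Metabolites, reactions (the S matrix), bounds and objective."""

    metabolites: dict[str, Metabolite]
    reactions: dict[str, Reaction]
    objective_id: str
    biomass_composition: dict[str, float] = field(
        default_factory=lambda: dict(BIOMASS_COMPOSITION))

    # -- structural queries -------------------------------------------------

    def is_exchange(self, rxn_id: str) -> bool:
        """An exchange touches exactly one metabolite, in compartment e."""
        rxn = self.reactions[rxn_id]
        if len(rxn.stoichiometry) != 1:
            return False
        (mid,) = rxn.stoichiometry
        return self.metabolites[mid].compartment == "e"

    def is_boundary(self, rxn_id: str) -> bool:
        """Exchange, biomass or other drain (exempt from mass balance)."""
        return (rxn_id == self.objective_id or self.is_exchange(rxn_id)
                or len(self.reactions[rxn_id].stoichiometry) == 1)

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions) plus row/column id orders."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coeff in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coeff
        return S, met_ids, rxn_ids

    # -- validation ---------------------------------------------------------

    def validate(self, tol: float = 1e-9) -> None:
        """Raise :class:`ModelError` on any structural defect."""
        if self.objective_id not in self.reactions:
            raise ModelError(f"objective {self.objective_id!r} not a reaction")
        for rid, rxn in self.reactions.items():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {rid!r} references unknown metabolite {mid!r}")
        bad = check_mass_balance(self, tol=tol)
        if bad:
            raise ModelError(f"unbalanced internal reactions: {bad[:5]}")
        cimb = biomass_carbon_imbalance(self, tol=tol)
        if abs(cimb) > max(tol, 1e-6):
            raise ModelError(f"biomass carbon imbalance {cimb:.3e} mmol C/g")


def check_mass_balance(model: StoichiometricModel,
                       tol: float = 1e-9) -> list[tuple[str, str, float]]:
    """Element balance check for every internal reaction.

    Returns ``(reaction id, element, imbalance)`` triples for each C, H,
    O or N imbalance larger than ``tol``.  Exchange reactions, other
    single-metabolite drains and the biomass reaction are exempt (the
    biomass carbon check lives in :func:`biomass_carbon_imbalance`).
    """
    problems: list[tuple[str, str, float]] = []
    for rid, rxn in model.reactions.items():
        if model.is_boundary(rid):
            continue
        for el in BALANCED_ELEMENTS:
            total = 0.0
            for mid, coeff in rxn.stoichiometry.items():
                met = model.metabolites.get(mid)
                if met is None:
                    raise ModelError(
                        f"reaction {rid!r} references unknown metabolite {mid!r}")
                total += coeff * met.formula.get(el, 0.0)
            if abs(total) > tol:
                problems.append((rid, el, total))
    return problems


def biomass_carbon_imbalance(model: StoichiometricModel,
                             tol: float = 1e-9) -> float:
    """Carbon drained by the biomass reaction per unit flux minus the
    carbon content implied by ``biomass_composition``.

    The biomass reaction is scaled per gram of cell dry weight, so one
    unit of flux must consume ``1000 / M_cmol`` mmol of carbon, where
    ``M_cmol`` is the gram-per-Cmol mass of the composition.  Returns
    the signed mismatch in mmol C per gram.
    """
    rxn = model.reactions[model.objective_id]
    carbon_in = 0.0
    for mid, coeff in rxn.stoichiometry.items():
        carbon_in -= coeff * model.metabolites[mid].formula.get("C", 0.0)
    expected = 1000.0 / cmol_mass(model.biomass_composition)
    return carbon_in - expected


# ---------------------------------------------------------------------------
# Core network definition
# ---------------------------------------------------------------------------

# (id, name, compartment, formula) -- formulas are BiGG charged species
_METABOLITES = [
    # extracellular
    ("glc__D_e", "D-glucose", "e", "C6H12O6"),
    ("xyl__D_e", "D-xylose", "e", "C5H10O5"),
    ("eg_e", "ethylene glycol", "e", "C6H12O6"),  # placeholder, fixed below
    ("glyclt_e", "glycolate", "e", "C2H3O3"),
    ("glx_e", "glyoxylate", "e", "C2H1O3"),
    ("o2_e", "O2", "e", "O2"),
    ("co2_e", "CO2", "e", "CO2"),
    ("nh4_e", "ammonium", "e", "H4N"),
    ("h2o_e", "H2O", "e", "H2O"),
    ("h_e", "H+", "e", "H"),
    # cytosol -- sugars and EG pathway
    ("glc__D_c", "D-glucose", "c", "C6H12O6"),
    ("xyl__D_c", "D-xylose", "c", "C5H10O5"),
    ("xylt_c", "xylitol", "c", "C5H12O5"),
    ("xylu__D_c", "D-xylulose", "c", "C5H10O5"),
    ("abt__D_c", "D-arabitol", "c", "C5H12O5"),
    ("rbl__D_c", "D-ribulose", "c", "C5H10O5"),
    ("eg_c", "ethylene glycol", "c", "C2H6O2"),
    ("gcald_c", "glycolaldehyde", "c", "C2H4O2"),
    ("glyclt_c", "glycolate", "c", "C2H3O3"),
    ("glx_c", "glyoxylate", "c", "C2H1O3"),
    # cytosol -- glycolysis / PPP
    ("g6p_c", "glucose 6-phosphate", "c", "C6H11O9P"),
    ("f6p_c", "fructose 6-phosphate", "c", "C6H11O9P"),
    ("fdp_c", "fructose 1,6-bisphosphate", "c", "C6H10O12P2"),
    ("dhap_c", "dihydroxyacetone phosphate", "c", "C3H5O6P"),
    ("g3p_c", "glyceraldehyde 3-phosphate", "c", "C3H5O6P"),
    ("13dpg_c", "1,3-bisphosphoglycerate", "c", "C3H4O10P2"),
    ("3pg_c", "3-phosphoglycerate", "c", "C3H4O7P"),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H2O6P"),
    ("pyr_c", "pyruvate", "c", "C3H3O3"),
    ("6pgl_c", "6-phosphogluconolactone", "c", "C6H9O9P"),
    ("6pgc_c", "6-phosphogluconate", "c", "C6H10O10P"),
    ("ru5p__D_c", "D-ribulose 5-phosphate", "c", "C5H9O8P"),
    ("xu5p__D_c", "D-xylulose 5-phosphate", "c", "C5H9O8P"),
    ("r5p_c", "ribose 5-phosphate", "c", "C5H9O8P"),
    ("xu1p__D_c", "D-xylulose 1-phosphate", "c", "C5H9O8P"),
    ("oaa_c", "oxaloacetate", "c", "C4H2O5"),
    ("akg_c", "2-oxoglutarate", "c", "C5H4O5"),
    ("glu__L_c", "L-glutamate", "c", "C5H8NO4"),
    ("gly_c", "glycine", "c", "C2H5NO2"),
    # cytosol -- cofactors and small species
    ("nad_c", "NAD+", "c", "C21H26N7O14P2"),
    ("nadh_c", "NADH", "c", "C21H27N7O14P2"),
    ("nadp_c", "NADP+", "c", "C21H25N7O17P3"),
    ("nadph_c", "NADPH", "c", "C21H26N7O17P3"),
    ("atp_c", "ATP", "c", "C10H12N5O13P3"),
    ("adp_c", "ADP", "c", "C10H12N5O10P2"),
    ("pi_c", "phosphate", "c", "HO4P"),
    ("h_c", "H+", "c", "H"),
    ("h2o_c", "H2O", "c", "H2O"),
    ("o2_c", "O2", "c", "O2"),
    ("co2_c", "CO2", "c", "CO2"),
    ("nh4_c", "ammonium", "c", "H4N"),
    # mitochondrion
    ("pyr_m", "pyruvate", "m", "C3H3O3"),
    ("accoa_m", "acetyl-CoA", "m", "C23H34N7O17P3S"),
    ("coa_m", "coenzyme A", "m", "C21H32N7O16P3S"),
    ("cit_m", "citrate", "m", "C6H5O7"),
    ("icit_m", "isocitrate", "m", "C6H5O7"),
    ("akg_m", "2-oxoglutarate", "m", "C5H4O5"),
    ("succoa_m", "succinyl-CoA", "m", "C25H35N7O19P3S"),
    ("succ_m", "succinate", "m", "C4H4O4"),
    ("fum_m", "fumarate", "m", "C4H2O4"),
    ("mal__L_m", "L-malate", "m", "C4H4O5"),
    ("oaa_m", "oxaloacetate", "m", "C4H2O5"),
    ("glx_m", "glyoxylate", "m", "C2H1O3"),
    ("glyclt_m", "glycolate", "m", "C2H3O3"),
    ("ala__L_m", "L-alanine", "m", "C3H7NO2"),
    ("gly_m", "glycine", "m", "C2H5NO2"),
    ("glu__L_m", "L-glutamate", "m", "C5H8NO4"),
    ("nad_m", "NAD+", "m", "C21H26N7O14P2"),
    ("nadh_m", "NADH", "m", "C21H27N7O14P2"),
    ("atp_m", "ATP", "m", "C10H12N5O13P3"),
    ("adp_m", "ADP", "m", "C10H12N5O10P2"),
    ("pi_m", "phosphate", "m", "HO4P"),
    ("h_m", "H+", "m", "H"),
    ("h2o_m", "H2O", "m", "H2O"),
    ("o2_m", "O2", "m", "O2"),
    ("co2_m", "CO2", "m", "CO2"),
    # peroxisome
    ("icit_p", "isocitrate", "p", "C6H5O7"),
    ("glx_p", "glyoxylate", "p", "C2H1O3"),
    ("succ_p", "succinate", "p", "C4H4O4"),
    ("glyclt_p", "glycolate", "p", "C2H3O3"),
    ("o2_p", "O2", "p", "O2"),
    ("h2o_p", "H2O", "p", "H2O"),
]
# fix the placeholder above (kept the tuple layout aligned for readability)
_METABOLITES[2] = ("eg_e", "ethylene glycol", "e", "C2H6O2")

_INF = 1000.0

# (id, name, stoichiometry, lb, ub, subsystem, cofactor)
_REACTIONS: list[tuple] = [
    # ---- exchanges (negative flux = uptake) ----
    ("EX_glc__D_e", "glucose exchange", {"glc__D_e": -1}, -10, _INF, "exchange", "none"),
    ("EX_xyl__D_e", "xylose exchange", {"xyl__D_e": -1}, -10, _INF, "exchange", "none"),
    ("EX_eg_e", "ethylene glycol exchange", {"eg_e": -1}, -10, _INF, "exchange", "none"),
    ("EX_glyclt_e", "glycolate exchange", {"glyclt_e": -1}, 0, _INF, "exchange", "none"),
    ("EX_o2_e", "O2 exchange", {"o2_e": -1}, -_INF, 0, "exchange", "none"),
    ("EX_co2_e", "CO2 exchange", {"co2_e": -1}, -_INF, _INF, "exchange", "none"),
    ("EX_nh4_e", "ammonium exchange", {"nh4_e": -1}, -_INF, 0, "exchange", "none"),
    ("EX_h2o_e", "H2O exchange", {"h2o_e": -1}, -_INF, _INF, "exchange", "none"),
    ("EX_h_e", "H+ exchange", {"h_e": -1}, -_INF, _INF, "exchange", "none"),
    # ---- transport ----
    ("GLCt", "glucose transport", {"glc__D_e": -1, "glc__D_c": 1}, 0, _INF, "transport", "none"),
    ("XYLt", "xylose transport", {"xyl__D_e": -1, "xyl__D_c": 1}, 0, _INF, "transport", "none"),
    ("T_eg", "ethylene glycol transport", {"eg_e": -1, "eg_c": 1}, 0, _INF, "transport", "none"),
    ("GLYCLTt", "glycolate transport", {"glyclt_c": -1, "glyclt_e": 1}, -_INF, _INF, "transport", "none"),
    ("O2t", "O2 diffusion", {"o2_e": -1, "o2_c": 1}, -_INF, _INF, "transport", "none"),
    ("CO2t", "CO2 diffusion", {"co2_c": -1, "co2_e": 1}, -_INF, _INF, "transport", "none"),
    ("NH4t", "ammonium transport", {"nh4_e": -1, "nh4_c": 1}, 0, _INF, "transport", "none"),
    ("H2Ot", "H2O diffusion", {"h2o_c": -1, "h2o_e": 1}, -_INF, _INF, "transport", "none"),
    ("Ht", "H+ exchange across membrane", {"h_c": -1, "h_e": 1}, -_INF, _INF, "transport", "none"),
    # ---- glycolysis ----
    ("HEX1", "hexokinase", {"glc__D_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1}, 0, _INF, "glycolysis", "none"),
    ("PGI", "phosphoglucose isomerase", {"g6p_c": -1, "f6p_c": 1}, -_INF, _INF, "glycolysis", "none"),
    ("PFK", "phosphofructokinase", {"f6p_c": -1, "atp_c": -1, "fdp_c": 1, "adp_c": 1, "h_c": 1}, 0, _INF, "glycolysis", "none"),
    ("FBA", "fructose-bisphosphate aldolase", {"fdp_c": -1, "dhap_c": 1, "g3p_c": 1}, -_INF, _INF, "glycolysis", "none"),
    ("TPI", "triose-phosphate isomerase", {"dhap_c": -1, "g3p_c": 1}, -_INF, _INF, "glycolysis", "none"),
    ("GAPD", "glyceraldehyde-3-phosphate dehydrogenase",
     {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "13dpg_c": 1, "nadh_c": 1, "h_c": 1}, -_INF, _INF, "glycolysis", "NAD"),
    ("PGK", "phosphoglycerate kinase", {"13dpg_c": -1, "adp_c": -1, "3pg_c": 1, "atp_c": 1}, -_INF, _INF, "glycolysis", "none"),
    ("ENO", "phosphoglycerate mutase + enolase (lumped)", {"3pg_c": -1, "pep_c": 1, "h2o_c": 1}, -_INF, _INF, "glycolysis", "none"),
    ("PYK", "pyruvate kinase", {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1}, 0, _INF, "glycolysis", "none"),
    # ---- pentose phosphate pathway ----
    ("G6PDH2r", "glucose-6-phosphate dehydrogenase",
     {"g6p_c": -1, "nadp_c": -1, "6pgl_c": 1, "nadph_c": 1, "h_c": 1}, 0, _INF, "ppp", "NADP"),
    ("PGL", "6-phosphogluconolactonase", {"6pgl_c": -1, "h2o_c": -1, "6pgc_c": 1, "h_c": 1}, 0, _INF, "ppp", "none"),
    ("GND", "6-phosphogluconate dehydrogenase",
     {"6pgc_c": -1, "nadp_c": -1, "ru5p__D_c": 1, "co2_c": 1, "nadph_c": 1}, 0, _INF, "ppp", "NADP"),
    ("RPE", "ribulose-5-phosphate 3-epimerase", {"ru5p__D_c": -1, "xu5p__D_c": 1}, -_INF, _INF, "ppp", "none"),
    ("RPI", "ribose-5-phosphate isomerase", {"ru5p__D_c": -1, "r5p_c": 1}, -_INF, _INF, "ppp", "none"),
    ("TKT_TAL", "non-oxidative PPP (lumped transketolase/transaldolase)",
     {"xu5p__D_c": -2, "r5p_c": -1, "f6p_c": 2, "g3p_c": 1}, -_INF, _INF, "ppp", "none"),
    # ---- xylose assimilation and arabitol side reactions ----
    ("XYLR", "xylose reductase (NADPH)",
     {"xyl__D_c": -1, "nadph_c": -1, "h_c": -1, "xylt_c": 1, "nadp_c": 1}, 0, _INF, "xylose", "NADP"),
    ("XYLTD_D", "xylitol dehydrogenase (NAD)",
     {"xylt_c": -1, "nad_c": -1, "xylu__D_c": 1, "nadh_c": 1, "h_c": 1}, -_INF, _INF, "xylose", "NAD"),
    ("XYLK", "xylulokinase", {"xylu__D_c": -1, "atp_c": -1, "xu5p__D_c": 1, "adp_c": 1, "h_c": 1}, 0, _INF, "xylose", "none"),
    ("DABT2D", "D-arabitol 2-dehydrogenase (NAD)",
     {"abt__D_c": -1, "nad_c": -1, "rbl__D_c": 1, "nadh_c": 1, "h_c": 1}, -_INF, _INF, "xylose", "NAD"),
    ("DABT4D", "D-arabitol 4-dehydrogenase (NADP)",
     {"abt__D_c": -1, "nadp_c": -1, "xylu__D_c": 1, "nadph_c": 1, "h_c": 1}, -_INF, _INF, "xylose", "NADP"),
    ("RBK_D", "D-ribulokinase", {"rbl__D_c": -1, "atp_c": -1, "ru5p__D_c": 1, "adp_c": 1, "h_c": 1}, 0, _INF, "xylose", "none"),
    # ---- pyruvate node / TCA cycle ----
    ("PYRt2m", "pyruvate mitochondrial transport", {"pyr_c": -1, "h_c": -1, "pyr_m": 1, "h_m": 1}, 0, _INF, "transport", "none"),
    ("PDHm", "pyruvate dehydrogenase",
     {"pyr_m": -1, "coa_m": -1, "nad_m": -1, "accoa_m": 1, "co2_m": 1, "nadh_m": 1}, 0, _INF, "tca", "NAD"),
    ("CSm", "citrate synthase",
     {"accoa_m": -1, "oaa_m": -1, "h2o_m": -1, "cit_m": 1, "coa_m": 1, "h_m": 1}, 0, _INF, "tca", "none"),
    ("ACONTm", "aconitase", {"cit_m": -1, "icit_m": 1}, -_INF, _INF, "tca", "none"),
    ("ICDHxm", "isocitrate dehydrogenase (NAD)",
     {"icit_m": -1, "nad_m": -1, "akg_m": 1, "co2_m": 1, "nadh_m": 1}, 0, _INF, "tca", "NAD"),
    ("AKGDm", "2-oxoglutarate dehydrogenase",
     {"akg_m": -1, "coa_m": -1, "nad_m": -1, "succoa_m": 1, "co2_m": 1, "nadh_m": 1}, 0, _INF, "tca", "NAD"),
    ("SUCOASm", "succinyl-CoA synthetase",
     {"succoa_m": -1, "adp_m": -1, "pi_m": -1, "succ_m": 1, "coa_m": 1, "atp_m": 1}, -_INF, _INF, "tca", "none"),
    ("SUCDm", "succinate dehydrogenase (lumped with FADH2 oxidation)",
     {"succ_m": -1, "o2_m": -0.5, "fum_m": 1, "h2o_m": 1}, 0, _INF, "tca", "none"),
    ("FUMm", "fumarase", {"fum_m": -1, "h2o_m": -1, "mal__L_m": 1}, -_INF, _INF, "tca", "none"),
    ("MDHm", "malate dehydrogenase",
     {"mal__L_m": -1, "nad_m": -1, "oaa_m": 1, "nadh_m": 1, "h_m": 1}, -_INF, _INF, "tca", "NAD"),
    ("PC", "pyruvate carboxylase",
     {"pyr_c": -1, "co2_c": -1, "atp_c": -1, "h2o_c": -1, "oaa_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 2}, 0, _INF, "anaplerosis", "none"),
    ("OAAtm", "oxaloacetate mitochondrial transport", {"oaa_c": -1, "oaa_m": 1}, 0, _INF, "transport", "none"),
    # ---- oxidative phosphorylation (lumped, P/O = 1.5) ----
    ("RESPm", "NADH oxidation + oxidative phosphorylation (lumped)",
     {"nadh_m": -1, "o2_m": -0.5, "adp_m": -1.5, "pi_m": -1.5, "h_m": -2.5,
      "nad_m": 1, "atp_m": 1.5, "h2o_m": 2.5}, 0, _INF, "oxphos", "NAD"),
    ("NADHtm", "cytosolic NADH shuttle (lumped)",
     {"nadh_c": -1, "nad_m": -1, "nad_c": 1, "nadh_m": 1}, 0, _INF, "transport", "NAD"),
    ("ATPtm", "ADP/ATP translocase", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1}, 0, _INF, "transport", "none"),
    ("PItm", "phosphate mitochondrial transport", {"pi_c": -1, "h_c": -1, "pi_m": 1, "h_m": 1}, 0, _INF, "transport", "none"),
    ("Htm", "proton leak (lumped)", {"h_c": -1, "h_m": 1}, -_INF, _INF, "transport", "none"),
    ("O2tm", "O2 diffusion (mitochondrion)", {"o2_c": -1, "o2_m": 1}, 0, _INF, "transport", "none"),
    ("CO2tm", "CO2 diffusion (mitochondrion)", {"co2_m": -1, "co2_c": 1}, -_INF, _INF, "transport", "none"),
    ("H2Otm", "H2O diffusion (mitochondrion)", {"h2o_c": -1, "h2o_m": 1}, -_INF, _INF, "transport", "none"),
    ("ATPM", "non-growth-associated maintenance",
     {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}, 1.0, _INF, "maintenance", "none"),
    # ---- glyoxylate shunt (peroxisome) ----
    ("ICITtmp", "isocitrate peroxisomal transport", {"icit_m": -1, "icit_p": 1}, 0, _INF, "transport", "none"),
    ("ICLp", "isocitrate lyase (peroxisome)", {"icit_p": -1, "glx_p": 1, "succ_p": 1}, 0, _INF, "glyoxylate", "none"),
    ("SUCCtpm", "succinate return transport", {"succ_p": -1, "succ_m": 1}, 0, _INF, "transport", "none"),
    ("GLXtp", "glyoxylate export to cytosol", {"glx_p": -1, "glx_c": 1}, 0, _INF, "transport", "none"),
    # ---- glycolate / glyoxylate redox ----
    ("GLYCLTDy", "glyoxylate reductase, cytosolic (NADPH)",
     {"glx_c": -1, "nadph_c": -1, "h_c": -1, "glyclt_c": 1, "nadp_c": 1}, -_INF, _INF, "glyoxylate", "NADP"),
    ("GLYCLTDxm", "glyoxylate reductase, mitochondrial (NADH)",
     {"glx_m": -1, "nadh_m": -1, "h_m": -1, "glyclt_m": 1, "nad_m": 1}, -_INF, _INF, "glyoxylate", "NAD"),
    ("GLYCLTtm", "glycolate mitochondrial transport", {"glyclt_c": -1, "glyclt_m": 1}, -_INF, _INF, "transport", "none"),
    ("GLYCLTtp", "glycolate peroxisomal transport", {"glyclt_c": -1, "glyclt_p": 1}, -_INF, _INF, "transport", "none"),
    ("GLYCDO1p", "glycolate oxidase (peroxisome, lumped with catalase)",
     {"glyclt_p": -1, "o2_p": -0.5, "glx_p": 1, "h2o_p": 1}, 0, _INF, "glyoxylate", "none"),
    ("O2tp", "O2 diffusion (peroxisome)", {"o2_c": -1, "o2_p": 1}, 0, _INF, "transport", "none"),
    ("H2Otp", "H2O diffusion (peroxisome)", {"h2o_p": -1, "h2o_c": 1}, -_INF, _INF, "transport", "none"),
    # ---- nitrogen assimilation / glycine via glyoxylate ----
    ("GDH", "glutamate dehydrogenase (NADPH)",
     {"akg_c": -1, "nh4_c": -1, "nadph_c": -1, "h_c": -1, "glu__L_c": 1, "h2o_c": 1, "nadp_c": 1}, 0, _INF, "nitrogen", "NADP"),
    ("AKGtm", "2-oxoglutarate transport", {"akg_m": -1, "akg_c": 1}, -_INF, _INF, "transport", "none"),
    ("GLUtm", "glutamate mitochondrial transport", {"glu__L_c": -1, "glu__L_m": 1}, -_INF, _INF, "transport", "none"),
    ("ALATA_m", "alanine transaminase (mitochondrial)",
     {"akg_m": -1, "ala__L_m": -1, "pyr_m": 1, "glu__L_m": 1}, -_INF, _INF, "nitrogen", "none"),
    ("AGTim", "alanine-glyoxylate aminotransferase (mitochondrial)",
     {"ala__L_m": -1, "glx_m": -1, "pyr_m": 1, "gly_m": 1}, 0, _INF, "glyoxylate", "none"),
    ("GLYtm", "glycine export from mitochondrion", {"gly_m": -1, "gly_c": 1}, 0, _INF, "transport", "none"),
]

# EG oxidation chain, parameterised by cofactor flavor
_EG_REACTIONS = {
    "NAD": [
        ("EGDH_NAD", "ethylene glycol dehydrogenase (NAD)",
         {"eg_c": -1, "nad_c": -1, "gcald_c": 1, "nadh_c": 1, "h_c": 1}, 0, _INF, "eg_pathway", "NAD"),
        ("GCALDD_NAD", "glycolaldehyde dehydrogenase (NAD)",
         {"gcald_c": -1, "nad_c": -1, "h2o_c": -1, "glyclt_c": 1, "nadh_c": 1, "h_c": 2}, 0, _INF, "eg_pathway", "NAD"),
    ],
    "NADP": [
        ("EGDH_NADP", "ethylene glycol dehydrogenase (NADP)",
         {"eg_c": -1, "nadp_c": -1, "gcald_c": 1, "nadph_c": 1, "h_c": 1}, 0, _INF, "eg_pathway", "NADP"),
        ("GCALDD_NADP", "glycolaldehyde dehydrogenase (NADP)",
         {"gcald_c": -1, "nadp_c": -1, "h2o_c": -1, "glyclt_c": 1, "nadph_c": 1, "h_c": 2}, 0, _INF, "eg_pathway", "NADP"),
    ],
}

# reductive glycolaldehyde reductase (GAH -> EG); physiological direction of
# the GRE2 homolog, kept closed by default because flux analysis is run on
# oxidative EG conditions.
_GRE2_REACTION = (
    "GRE2R", "glycolaldehyde reductase (NADPH, closed by default)",
    {"gcald_c": -1, "nadph_c": -1, "h_c": -1, "eg_c": 1, "nadp_c": 1},
    0, 0, "eg_pathway", "NADP")

# optional xylulose-1-phosphate aldolase route: D-xylulose -> DHAP + GAH
_XU1P_REACTIONS = [
    ("XYLK1", "xylulokinase-1P",
     {"xylu__D_c": -1, "atp_c": -1, "xu1p__D_c": 1, "adp_c": 1, "h_c": 1}, 0, _INF, "xu1p_route", "none"),
    ("XU1PA", "xylulose-1-phosphate aldolase",
     {"xu1p__D_c": -1, "dhap_c": 1, "gcald_c": 1}, 0, _INF, "xu1p_route", "none"),
]

# optional glyoxylate secretion
_GLX_SECRETION = [
    ("GLXt", "glyoxylate export", {"glx_c": -1, "glx_e": 1}, 0, _INF, "transport", "none"),
    ("EX_glx_e", "glyoxylate exchange", {"glx_e": -1}, 0, _INF, "exchange", "none"),
]

#: reaction identifiers highlighted in the reduced network figure legend
FIGURE_REACTION_IDS = (
    "AGTim", "DABT2D", "DABT4D", "EX_eg_e", "EX_glyclt_e", "EX_xyl__D_e",
    "GAPD", "GLYCDO1p", "GLYCLTt", "GLYCLTDy", "GLYCLTDxm", "GLYCLTtm",
    "GLXtp", "ICLp", "RPE", "T_eg", "TPI", "XYLTD_D", "XYLK", "XYLR", "XYLt",
)

# per-Cmol biomass precursor demands; scaled per gram at build time.
# carbon: 0.05 g6p (0.3 C) + 0.1 gly (0.2 C) + 0.1 glu (0.5 C) = 1.0 Cmol;
# nitrogen: 0.1 (gly) + 0.1 (glu) = 0.2 mol, matching CH1.8O0.5N0.2.
# The model carries no phosphate source (the ATP/ADP/Pi pool is catalytic),
# so the g6p phosphate is returned as Pi: 1.5 (from ATP) + 0.05 (from g6p).
_BIOMASS_PER_CMOL = {
    "g6p_c": -0.05, "gly_c": -0.1, "glu__L_c": -0.1,
    "nadph_c": -0.4, "atp_c": -1.5, "h2o_c": -0.95,
    "nadp_c": 0.4, "adp_c": 1.5, "pi_c": 1.55, "h_c": 0.85,
}
#: growth-associated ATP demand (mol/Cmol) and NADPH demand (mol/Cmol,
#: the lipid-synthesis sink) are the -1.5 and -0.4 entries above.


def build_core_model(eg_cofactors: Iterable[str] = ("NAD", "NADP"),
                     xylulose1p_route: bool = False,
                     glyoxylate_secretion: bool = False,
                     nadph_per_cmol: float | None = None,
                     atp_per_cmol: float | None = None,
                     close_ga_oxidation: bool = False) -> StoichiometricModel:
    """Assemble the reduced core model.

    Parameters
    ----------
    eg_cofactors
        Non-empty subset of ``{"NAD", "NADP"}`` choosing which flavors of
        the two-step EG -> GAH -> GA oxidation chain are present.
    xylulose1p_route
        Include the hypothetical D-xylulose-1P aldolase route producing
        cytosolic glycolaldehyde from xylose carbon.
    glyoxylate_secretion
        Include a glyoxylate exchange so excess shunt flux may be secreted.
    nadph_per_cmol, atp_per_cmol
        Override the biomass NADPH (default 0.4 mol/Cmol) and ATP
        (default 1.5 mol/Cmol) demands.
    close_ga_oxidation
        Restrict both glyoxylate reductases to the GOX -> GA direction,
        reflecting the observed 100 % molar GA yield (no re-oxidation).
    """
    cofactors = sorted(set(eg_cofactors))
    if not cofactors:
        raise ModelError("at least one EG-oxidation cofactor flavor is required")
    for cof in cofactors:
        if cof not in ("NAD", "NADP"):
            raise ModelError(f"unknown EG cofactor flavor {cof!r}")

    metabolites: dict[str, Metabolite] = {}
    for mid, name, comp, formula in _METABOLITES:
        metabolites[mid] = Metabolite(mid, name, comp, parse_formula(formula))

    raw: list[tuple] = list(_REACTIONS)
    for cof in cofactors:
        raw.extend(_EG_REACTIONS[cof])
    raw.append(_GRE2_REACTION)
    if xylulose1p_route:
        raw.extend(_XU1P_REACTIONS)
    if glyoxylate_secretion:
        raw.extend(_GLX_SECRETION)

    reactions: dict[str, Reaction] = {}
    for rid, name, stoich, lb, ub, subsystem, cof in raw:
        if rid in reactions:
            raise ModelError(f"duplicate reaction id {rid!r}")
        reactions[rid] = Reaction(rid, name, dict(stoich), float(lb), float(ub),
                                  subsystem, cof)

    if close_ga_oxidation:
        # forward direction is GOX + NAD(P)H -> GA; forbid the reverse
        reactions["GLYCLTDy"].lower_bound = 0.0
        reactions["GLYCLTDxm"].lower_bound = 0.0
        # and the peroxisomal oxidase consuming GA
        reactions["GLYCDO1p"].upper_bound = 0.0

    # biomass, scaled from per-Cmol demands to per-gram CDW (mmol/g)
    biomass = dict(_BIOMASS_PER_CMOL)
    if nadph_per_cmol is not None:
        delta = nadph_per_cmol - (-biomass["nadph_c"])
        biomass["nadph_c"] -= delta
        biomass["nadp_c"] += delta
        biomass["h_c"] -= delta  # reducing equivalents enter the lipid sink
    if atp_per_cmol is not None:
        delta = atp_per_cmol - (-biomass["atp_c"])
        biomass["atp_c"] -= delta
        biomass["adp_c"] += delta
        biomass["pi_c"] += delta
        biomass["h2o_c"] -= delta
        biomass["h_c"] += delta
    scale = 1000.0 / cmol_mass(BIOMASS_COMPOSITION)
    stoich = {mid: coeff * scale for mid, coeff in biomass.items()}
    reactions["BIOMASS"] = Reaction(
        "BIOMASS", "biomass synthesis (1 g CDW per unit flux)",
        stoich, 0.0, _INF, "biomass", "none")

    model = StoichiometricModel(metabolites, reactions, "BIOMASS")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _num_to_str(x: float) -> str:
    return repr(float(x))


def equation_string(rxn: Reaction) -> str:
    """Human-readable equation, e.g. ``eg_c + nad_c --> gcald_c + ...``."""
    def side(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items)
    subs = sorted((m, c) for m, c in rxn.stoichiometry.items() if c < 0)
    prods = sorted((m, c) for m, c in rxn.stoichiometry.items() if c > 0)
    arrow = "<=>" if rxn.reversible else "-->"
    return f"{side(subs)} {arrow} {side(prods)}"


def write_model(model: StoichiometricModel, path: str | Path) -> tuple[Path, Path]:
    """Write the model as a JSON document plus a TSV reaction table.

    ``path`` names the JSON file; the TSV is written next to it with a
    ``.tsv`` suffix.  Numbers are stored as decimal strings (shortest
    round-trip ``repr``) so that write/read is bit-for-bit identity.
    """
    json_path = Path(path)
    tsv_path = json_path.with_suffix(".tsv")
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "objective_id": model.objective_id,
        "biomass_composition": {el: _num_to_str(n)
                                for el, n in model.biomass_composition.items()},
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "formula": {el: _num_to_str(n) for el, n in m.formula.items()}}
            for m in model.metabolites.values()],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": {mid: _num_to_str(c)
                               for mid, c in r.stoichiometry.items()},
             "lower_bound": _num_to_str(r.lower_bound),
             "upper_bound": _num_to_str(r.upper_bound),
             "subsystem": r.subsystem, "cofactor": r.cofactor}
            for r in model.reactions.values()],
    }
    json_path.write_text(json.dumps(doc, indent=1) + "\n")
    lines = ["id\tequation\tlb\tub\tsubsystem\tcofactor"]
    for r in model.reactions.values():
        lines.append("\t".join([r.id, equation_string(r),
                                _num_to_str(r.lower_bound),
                                _num_to_str(r.upper_bound),
                                r.subsystem, r.cofactor]))
    tsv_path.write_text("\n".join(lines) + "\n")
    return json_path, tsv_path


def read_model(path: str | Path) -> StoichiometricModel:
    """Read a model JSON document written by :func:`write_model`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelError(f"malformed model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelError(
            f"model schema version mismatch: file has {version!r}, "
            f"expected {MODEL_SCHEMA_VERSION!r}")
    metabolites: dict[str, Metabolite] = {}
    for m in doc["metabolites"]:
        if m["id"] in metabolites:
            raise ModelError(f"duplicate metabolite id {m['id']!r}")
        metabolites[m["id"]] = Metabolite(
            m["id"], m["name"], m["compartment"],
            {el: float(v) for el, v in m["formula"].items()})
    reactions: dict[str, Reaction] = {}
    for r in doc["reactions"]:
        if r["id"] in reactions:
            raise ModelError(f"duplicate reaction id {r['id']!r}")
        for mid in r["stoichiometry"]:
            if mid not in metabolites:
                raise ModelError(
                    f"reaction {r['id']!r} references unknown metabolite {mid!r}")
        reactions[r["id"]] = Reaction(
            r["id"], r["name"],
            {mid: float(v) for mid, v in r["stoichiometry"].items()},
            float(r["lower_bound"]), float(r["upper_bound"]),
            r.get("subsystem", ""), r.get("cofactor", "none"))
    model = StoichiometricModel(
        metabolites, reactions, doc["objective_id"],
        {el: float(v) for el, v in doc["biomass_composition"].items()})
    if model.objective_id not in reactions:
        raise ModelError(f"objective {model.objective_id!r} not in reactions")
    return model
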