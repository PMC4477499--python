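"""Constraint-based metabolic network container, loaders, and the toy fixture.

A :class:`MetabolicNetwork` is a plain stoichiometric description — sparse
S matrix, per-reaction flux bounds, and a role map that names the exchange
reactions the reactor model needs (CO, H2, CO2, ethanol, acetate, biomass
growth, ATP maintenance).  Genome-scale models are read through cobrapy
(SBML Level 3 / FBC or COBRA-JSON); the bundled toy Wood-Ljungdahl network
is constructed programmatically and can be round-tripped through
COBRA-JSON.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ROLES",
    "DEFAULT_ROLE_IDS",
    "MetabolicNetwork",
    "RoleMappingError",
    "ModelFormatError",
    "load_metabolic_model",
    "toy_wlp_network",
]

#: Roles the reactor model must be able to resolve to exchange reactions.
ROLES = ("co", "h2", "co2", "ethanol", "acetate", "biomass", "atpm")

#: Default reaction-id patterns (BiGG spellings).  The biomass entry is a
#: prefix pattern; all others are exact ids.
DEFAULT_ROLE_IDS = {
    "co": "EX_co_e",
    "h2": "EX_h2_e",
    "co2": "EX_co2_e",
    "ethanol": "EX_etoh_e",
    "acetate": "EX_ac_e",
    "atpm": "ATPM",
    "biomass": "BIOMASS*",
}

#: mmol of carbon per mmol of each exchanged species (toy network
#: bookkeeping; BIOMASS is 10 acetyl-CoA at 2 C each).
TOY_CARBON_CONTENT = {
    "co": 1.0,
    "co2": 1.0,
    "ethanol": 2.0,
    "acetate": 2.0,
    "biomass": 20.0,
}


class RoleMappingError(KeyError):
    """An exchange role could not be resolved to a unique reaction id."""


class ModelFormatError(ValueError):
    """The model file could not be parsed under the named standard."""


@dataclass
class MetabolicNetwork:
    """Stoichiometry, bounds, and named exchange roles of a metabolic model."""

    reactions: list[str]
    metabolites: list[str]
    stoichiometry: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    exchanges: dict[str, str]
    name: str = "network"
    source_checksum: str | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {rid: j for j, rid in enumerate(self.reactions)}
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.validate()

    # -- basic queries -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def biomass_reaction(self) -> str:
        return self.exchanges["biomass"]

    def index(self, reaction_id: str) -> int:
        return self._index[reaction_id]

    def role_index(self, role: str) -> int:
        return self.index(self.exchanges[role])

    def validate(self) -> None:
        n_m, n_r = self.stoichiometry.shape
        if (n_m, n_r) != (self.n_metabolites, self.n_reactions):
            raise ValueError(
                f"stoichiometric matrix is {self.stoichiometry.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})"
            )
        if self.lower_bounds.shape != (n_r,) or self.upper_bounds.shape != (n_r,):
            raise ValueError("bound arrays must have one entry per reaction")
        if np.any(self.lower_bounds > self.upper_bounds):
            raise ValueError("lower bound exceeds upper bound for some reaction")
        missing = [r for r in ROLES if r not in self.exchanges]
        if missing:
            raise RoleMappingError(f"unresolved exchange roles: {missing}")
        for role, rid in self.exchanges.items():
            if rid not in self._index:
                raise RoleMappingError(
                    f"role {role!r} maps to unknown reaction {rid!r}"
                )
        if self.lower_bounds[self.role_index("atpm")] <= 0:
            raise ValueError(
                "ATP maintenance reaction must have a strictly positive lower bound"
            )

    # -- cobra interop -------------------------------------------------
    def to_cobra_model(self):
        """Materialize as a cobrapy model (used for JSON/SBML export)."""
        import cobra

        model = cobra.Model(self.name)
        mets = {}
        for mid in self.metabolites:
            m = cobra.Metabolite(mid)
            m.compartment = "c"
            mets[mid] = m
        model.add_metabolites(list(mets.values()))
        coo = self.stoichiometry.tocoo()
        per_rxn: dict[int, dict[str, float]] = {j: {} for j in range(self.n_reactions)}
        for i, j, v in zip(coo.row, coo.col, coo.data):
            per_rxn[j][self.metabolites[i]] = float(v)
        rxns = []
        for j, rid in enumerate(self.reactions):
            r = cobra.Reaction(rid)
            r.lower_bound = float(self.lower_bounds[j])
            r.upper_bound = float(self.upper_bounds[j])
            rxns.append(r)
        model.add_reactions(rxns)
        for j, rid in enumerate(self.reactions):
            model.reactions.get_by_id(rid).add_metabolites(
                {mets[mid]: v for mid, v in per_rxn[j].items()}
            )
        model.objective = self.exchanges["biomass"]
        return model

    def to_json(self, path: str | Path) -> None:
        """Serialize to COBRA-JSON."""
        import cobra.io

        cobra.io.save_json_model(self.to_cobra_model(), str(path))


def _match_role(role: str, pattern: str, reaction_ids: list[str]) -> str:
    if pattern.endswith("*"):
        prefix = pattern[:-1]
        hits = [rid for rid in reaction_ids if rid.startswith(prefix)]
    else:
        hits = [rid for rid in reaction_ids if rid == pattern]
    if len(hits) != 1:
        raise RoleMappingError(
            f"role {role!r}: pattern {pattern!r} matched {len(hits)} reactions"
        )
    return hits[0]


def from_cobra_model(
    model,
    role_ids: dict[str, str] | None = None,
    name: str | None = None,
    checksum: str | None = None,
) -> MetabolicNetwork:
    """Convert a cobrapy model into a validated :class:`MetabolicNetwork`."""
    patterns = dict(DEFAULT_ROLE_IDS)
    if role_ids:
        patterns.update(role_ids)
    reaction_ids = [r.id for r in model.reactions]
    metabolite_ids = [m.id for m in model.metabolites]
    met_index = {mid: i for i, mid in enumerate(metabolite_ids)}
    rows, cols, data = [], [], []
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    for j, rxn in enumerate(model.reactions):
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        for met, coef in rxn.metabolites.items():
            rows.append(met_index[met.id])
            cols.append(j)
            data.append(float(coef))
    S = sp.csc_matrix(
        (data, (rows, cols)), shape=(len(metabolite_ids), len(reaction_ids))
    )
    unresolved = []
    exchanges = {}
    for role in ROLES:
        try:
            exchanges[role] = _match_role(role, patterns[role], reaction_ids)
        except RoleMappingError:
            unresolved.append(role)
    if unresolved:
        raise RoleMappingError(f"unresolved exchange roles: {unresolved}")
    return MetabolicNetwork(
        reactions=reaction_ids,
        metabolites=metabolite_ids,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        exchanges=exchanges,
        name=name or model.id or "network",
        source_checksum=checksum,
    )


def load_metabolic_model(
    source: str | Path,
    format: str | None = None,
    role_ids: dict[str, str] | None = None,
) -> MetabolicNetwork:
    """Load an SBML or COBRA-JSON model and resolve the exchange roles.

    ``format`` may be ``"sbml"`` or ``"json"``; when omitted it is sniffed
    from the file extension.  The file's SHA-256 checksum is recorded on
    the returned network for run metadata.
    """
    import cobra.io

    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    checksum = hashlib.sha256(path.read_bytes()).hexdigest()
    try:
        if format == "json":
            model = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown model format {format!r}")
    except ModelFormatError:
        raise
    except Exception as exc:  # parser errors vary by backend
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc
    return from_cobra_model(model, role_ids, name=path.stem, checksum=checksum)


def toy_wlp_network() -> MetabolicNetwork:
    """Lumped Wood-Ljungdahl toy network for an acetogen on CO/H2/CO2.

    Eight internal reactions over five internal pools (acetyl-CoA, ATP,
    reducing equivalents RED, internal CO2, internal acetate) plus six
    exchange reactions.  Carbon fixation runs CO/H2 oxidation into RED,
    the reductive acetyl-CoA pathway (2 CO2 + 8 RED -> acetyl-CoA),
    substrate-level ATP via acetate kinase, and ethanol from acetate via
    the AOR route (acetate + 4 RED -> ethanol).  Net conversions are the
    canonical syngas-fermentation stoichiometries:

    * 4 CO -> acetate + 2 CO2 (+ 1 ATP)
    * 6 CO -> ethanol + 4 CO2
    * 2 CO2 + 6 H2 -> ethanol

    so electron-rich (H2-heavy) uptake favors ethanol and electron-poor
    uptake favors acetate + CO2, and growth collapses when the ATP
    maintenance demand (lower bound 0.45 mmol/gDW/h) cannot be met.
    The BIO flux is the growth rate in 1/h (1 mmol BIOMASS == 1 gDW).
    """
    metabolites = [
        "ACCOA", "ATP", "RED", "CO2_c", "AC_c",
        "CO", "H2", "CO2", "ETOH", "AC", "BIOMASS",
    ]
    big = 1000.0
    # (id, {metabolite: coeff}, lb, ub)
    reactions = [
        ("CODH", {"CO": -1, "CO2_c": 1, "RED": 2}, 0.0, big),
        ("HYD", {"H2": -1, "RED": 2}, 0.0, big),
        ("WLP", {"CO2_c": -2, "RED": -8, "ACCOA": 1}, 0.0, big),
        ("ACK", {"ACCOA": -1, "AC_c": 1, "ATP": 1}, 0.0, big),
        ("AOR", {"AC_c": -1, "RED": -4, "ETOH": 1}, 0.0, big),
        ("ACT", {"AC_c": -1, "AC": 1}, 0.0, big),
        ("CO2T", {"CO2_c": -1, "CO2": 1}, -big, big),
        ("BIO", {"ACCOA": -10, "ATP": -20, "BIOMASS": 1}, 0.0, big),
        ("ATPM", {"ATP": -1}, 0.45, big),
        ("EX_co", {"CO": -1}, -big, 0.0),
        ("EX_h2", {"H2": -1}, -big, 0.0),
        ("EX_co2", {"CO2": -1}, -big, big),
        ("EX_etoh", {"ETOH": -1}, 0.0, big),
        ("EX_ac", {"AC": -1}, 0.0, big),
        ("EX_biomass", {"BIOMASS": -1}, 0.0, big),
    ]
    met_index = {m: i for i, m in enumerate(metabolites)}
    rows, cols, data = [], [], []
    lb = np.empty(len(reactions))
    ub = np.empty(len(reactions))
    for j, (_, stoich, lo, hi) in enumerate(reactions):
        lb[j], ub[j] = lo, hi
        for mid, coef in stoich.items():
            rows.append(met_index[mid])
            cols.append(j)
            data.append(float(coef))
    S = sp.csc_matrix(
        (data, (rows, cols)), shape=(len(metabolites), len(reactions))
    )
    return MetabolicNetwork(
        reactions=[r[0] for r in reactions],
        metabolites=metabolites,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        exchanges={
            "co": "EX_co",
            "h2": "EX_h2",
            "co2": "EX_co2",
            "ethanol": "EX_etoh",
            "acetate": "EX_ac",
            "biomass": "EX_biomass",
            "atpm": "ATPM",
        },
        name="toy_wlp",
    )
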