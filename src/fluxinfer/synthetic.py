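"""Synthetic toy metabolic networks with tunable substrate-signature overlap.

The generator emulates the structure that makes inverse environment prediction
work on a real genome-scale network: every substrate enters through its own
exchange + transport pair, flows down a *private* internal pathway, and merges
into a *shared core* (a TCA-cycle stand-in) that produces the carbon and
nitrogen precursors consumed by biomass. The ``overlap`` knob moves reactions
from the private pathways into a shared per-role tail:

* ``overlap = 0`` — pathways fully disjoint; each substrate has a unique
  internal flux signature and is perfectly identifiable.
* ``overlap = 1`` — all substrates of a role feed the shared tail directly;
  internal fluxes are identical across same-role substrates and no classifier
  can beat random guessing on that axis.

All stoichiometric coefficients are +/-1 so optimal fluxes have exact closed
forms (see :func:`toy_ground_truth`), usable as an independent oracle for the
LP solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .environments import SubstratePool
from .model import MetabolicModel

__all__ = ["ToyNetworkSpec", "generate_toy_model", "toy_ground_truth"]


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Parameters of a generated toy network.

    pathway_length is the number of internal reactions between a substrate's
    transport and the role hub; ``overlap`` is the fraction of those reactions
    shared across substrates of the same role; ``core_size`` is the number of
    shared core reactions between each role hub and its biomass precursor.
    """

    n_carbon: int = 3
    n_nitrogen: int = 3
    pathway_length: int = 3
    overlap: float = 0.0
    core_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_carbon < 2 or self.n_nitrogen < 2:
            raise ValueError("need at least 2 substrates per role")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        if self.pathway_length < 1 or self.core_size < 1:
            raise ValueError("pathway_length and core_size must be >= 1")

    @property
    def n_shared_tail(self) -> int:
        return round(self.overlap * self.pathway_length)

    @property
    def n_private(self) -> int:
        return self.pathway_length - self.n_shared_tail

    def substrate_names(self, role: str) -> list[str]:
        n = self.n_carbon if role == "C" else self.n_nitrogen
        return [f"{role.lower()}{i + 1}" for i in range(n)]

    def exchange_id(self, substrate: str) -> str:
        return f"EX_{substrate}_e"

    def private_pathway(self, substrate: str) -> list[str]:
        """Internal reaction ids of this substrate's private pathway."""
        return [f"P_{substrate}_{j + 1}" for j in range(self.n_private)]


def _build(spec: ToyNetworkSpec):
    mets: list[str] = []
    rxns: list[dict] = []

    def add_met(mid):
        if mid not in mets:
            mets.append(mid)
        return mid

    def add_rxn(rid, stoich, lb=0.0, ub=1000.0, subsystem="", obj=0.0):
        rxns.append(
            dict(id=rid, stoich=stoich, lb=lb, ub=ub, subsystem=subsystem, obj=obj)
        )

    pools = {}
    for role in ("C", "N"):
        prec = add_met(f"prec_{role}_c")
        hub = add_met(f"hub_{role}_c")
        # shared core: hub -> ... -> precursor
        prev = hub
        for j in range(spec.core_size):
            nxt = prec if j == spec.core_size - 1 else add_met(f"core_{role}_{j + 1}_c")
            add_rxn(f"CORE_{role}_{j + 1}", {prev: -1.0, nxt: 1.0}, subsystem="Core")
            prev = nxt
        # shared pathway tail: merge -> ... -> hub
        k = spec.n_shared_tail
        entry = hub
        if k:
            entry = add_met(f"merge_{role}_c")
            prev = entry
            for j in range(k):
                nxt = hub if j == k - 1 else add_met(f"tail_{role}_{j + 1}_c")
                add_rxn(f"SH_{role}_{j + 1}", {prev: -1.0, nxt: 1.0}, subsystem="SharedTail")
                prev = nxt

        exchanges = []
        for sub in spec.substrate_names(role):
            ext = add_met(f"{sub}_e")
            ex_id = spec.exchange_id(sub)
            add_rxn(ex_id, {ext: -1.0}, lb=0.0, ub=1000.0, subsystem="Exchange")
            exchanges.append(ex_id)
            if spec.n_private:
                cyt = add_met(f"{sub}_c")
                add_rxn(f"TR_{sub}", {ext: -1.0, cyt: 1.0}, subsystem="Transport")
                prev = cyt
                for j, pid in enumerate(spec.private_pathway(sub)):
                    last = j == spec.n_private - 1
                    nxt = entry if last else add_met(f"q_{sub}_{j + 1}_c")
                    add_rxn(pid, {prev: -1.0, nxt: 1.0}, subsystem="Pathway")
                    prev = nxt
            else:
                # full overlap: transport feeds the shared entry directly
                add_rxn(f"TR_{sub}", {ext: -1.0, entry: 1.0}, subsystem="Transport")
        pools[role] = exchanges

    add_rxn(
        "BIOMASS_toy",
        {"prec_C_c": -1.0, "prec_N_c": -1.0},
        subsystem="Biomass",
        obj=1.0,
    )
    return mets, rxns, pools


def generate_toy_model(spec: ToyNetworkSpec) -> tuple[MetabolicModel, SubstratePool]:
    """Build a toy model and its substrate pool from a spec.

    The returned model satisfies all :class:`~fluxinfer.model.MetabolicModel`
    invariants and is feasible (positive biomass) under any single carbon +
    single nitrogen environment.
    """
    mets, rxns, pools = _build(spec)
    met_index = {m: i for i, m in enumerate(mets)}
    S = sparse.lil_matrix((len(mets), len(rxns)))
    for j, r in enumerate(rxns):
        for mid, coeff in r["stoich"].items():
            S[met_index[mid], j] = coeff
    model = MetabolicModel(
        metabolite_ids=mets,
        reaction_ids=[r["id"] for r in rxns],
        S=S.tocsc(),
        lower_bounds=np.array([r["lb"] for r in rxns]),
        upper_bounds=np.array([r["ub"] for r in rxns]),
        objective_coeffs=np.array([r["obj"] for r in rxns]),
        subsystem=[r["subsystem"] for r in rxns],
    )
    pool = SubstratePool(carbon_pool=tuple(pools["C"]), nitrogen_pool=tuple(pools["N"]))
    return model, pool


def toy_ground_truth(
    spec: ToyNetworkSpec,
    carbon_substrate: str,
    nitrogen_substrate: str,
    carbon_uptake: float = 20.0,
    nitrogen_uptake: float = 20.0,
    impurity_uptakes_C: dict[str, float] | None = None,
    impurity_uptakes_N: dict[str, float] | None = None,
) -> tuple[dict[str, float], float]:
    """Closed-form optimal fluxes for a zero-overlap toy environment.

    With unit stoichiometry every pathway is a simple chain, so the optimum is
    a min-flow: biomass equals the smaller of total carbon and total nitrogen
    supply, the limiting role's pathways all run at capacity, and a non-limiting
    role must have a single active substrate for its flux split to be unique.

    Returns (fluxes keyed by reaction id — unlisted reactions carry zero),
    biomass.

    Raises
    ------
    ValueError
        For ``overlap > 0`` (no closed form) or a degenerate flux split.
    """
    if spec.overlap != 0.0:
        raise ValueError("closed-form ground truth requires overlap = 0")
    up_C = {carbon_substrate: carbon_uptake, **(impurity_uptakes_C or {})}
    up_N = {nitrogen_substrate: nitrogen_uptake, **(impurity_uptakes_N or {})}
    cap_C, cap_N = sum(up_C.values()), sum(up_N.values())
    biomass = min(cap_C, cap_N)

    fluxes: dict[str, float] = {"BIOMASS_toy": biomass}
    for role, uptakes, cap in (("C", up_C, cap_C), ("N", up_N, cap_N)):
        if cap > biomass and len(uptakes) > 1:
            raise ValueError(
                f"degenerate split: role {role} is non-limiting with multiple "
                f"active substrates"
            )
        for sub, u in uptakes.items():
            path_flux = u if cap == biomass else biomass
            fluxes[spec.exchange_id(sub)] = -path_flux
            fluxes[f"TR_{sub}"] = path_flux
            for pid in spec.private_pathway(sub):
                fluxes[pid] = path_flux
        for j in range(spec.core_size):
            fluxes[f"CORE_{role}_{j + 1}"] = biomass
    return fluxes, biomass
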