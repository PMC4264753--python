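"""Constraint-based metabolic models: containers, readers, and reaction classification.

A :class:`MetabolicModel` is a plain numerical view of a genome-scale (or toy)
reconstruction: the sparse stoichiometric matrix ``S`` (metabolites x reactions),
per-reaction flux bounds, the biomass objective, and enough annotation
(subsystem strings, metabolite compartments) to sort reactions into the four
classes that matter for inverse environment prediction: *exchange* reactions
(boundary uptake/secretion pseudo-reactions), *transport* reactions (movement
between compartments), the *biomass* pseudo-reaction, and the remaining
*internal* reactions whose fluxes serve as predictor features.

Parsing of the standard formats (SBML Level 3 FBC, BiGG JSON) is delegated to
cobrapy; the toy-model writer emits BiGG-schema JSON so that fixtures round-trip
through the same reader.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import sparse

__all__ = [
    "MetabolicModel",
    "ReactionPartition",
    "ModelFormatError",
    "ModelConfigurationError",
    "load_model",
    "write_bigg_json",
    "classify_reactions",
]

#: default compartment suffix convention of BiGG identifiers ("glc__D_e" -> "_e")
BIGG_COMPARTMENT_RE = r"^(?P<species>.+)_(?P<compartment>[a-z][a-z0-9]?)$"

LARGE_BOUND = 1000.0


class ModelFormatError(ValueError):
    """The file does not parse under the named standard."""


class ModelConfigurationError(ValueError):
    """The model parsed but is not usable (e.g. no or ambiguous objective)."""


@dataclass
class MetabolicModel:
    """Numerical container for a constraint-based model.

    Attributes
    ----------
    metabolite_ids, reaction_ids : list of str
        Row and column labels of ``S``.
    S : scipy.sparse.csc_matrix
        Stoichiometric matrix, metabolites x reactions.
    lower_bounds, upper_bounds : ndarray
        Per-reaction flux bounds in mmol gDW^-1 hr^-1.
    objective_coeffs : ndarray
        Per-reaction objective weights; 1 on the biomass reaction, 0 elsewhere.
    subsystem : list of str
        Per-reaction pathway annotation (may be empty strings).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: sparse.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    objective_coeffs: np.ndarray
    subsystem: list[str] = field(default_factory=list)
    compartment_regex: str = BIGG_COMPARTMENT_RE

    def __post_init__(self) -> None:
        n = len(self.reaction_ids)
        m = len(self.metabolite_ids)
        self.S = sparse.csc_matrix(self.S, dtype=float)
        if self.S.shape != (m, n):
            raise ValueError(
                f"S has shape {self.S.shape}, expected ({m}, {n}) from the id lists"
            )
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        for name, arr in (
            ("lower_bounds", self.lower_bounds),
            ("upper_bounds", self.upper_bounds),
            ("objective_coeffs", self.objective_coeffs),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} has length {arr.shape}, expected {n}")
        if np.any(self.lower_bounds > self.upper_bounds):
            bad = np.flatnonzero(self.lower_bounds > self.upper_bounds)
            raise ValueError(
                f"lower bound exceeds upper bound for {self.reaction_ids[bad[0]]}"
            )
        if not self.subsystem:
            self.subsystem = [""] * n
        if len(self.subsystem) != n:
            raise ValueError("subsystem annotation length mismatch")
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        if len(self._rxn_index) != n:
            raise ValueError("duplicate reaction identifiers")

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction id: {reaction_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return replace(
            self,
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            objective_coeffs=self.objective_coeffs.copy(),
            subsystem=list(self.subsystem),
        )

    def with_bounds(self, bounds: dict[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with the given per-reaction (lb, ub) overrides."""
        out = self.copy()
        for rid, (lb, ub) in bounds.items():
            i = out.reaction_index(rid)
            out.lower_bounds[i] = lb
            out.upper_bounds[i] = ub
        return out

    def split_species_compartment(self, metabolite_id: str) -> tuple[str, str]:
        """Split a metabolite id into (species, compartment) per the configured regex."""
        m = re.match(self.compartment_regex, metabolite_id)
        if m is None:
            return metabolite_id, ""
        return m.group("species"), m.group("compartment")


@dataclass(frozen=True)
class ReactionPartition:
    """Disjoint, exhaustive split of a model's reactions by role."""

    exchange_ids: tuple[str, ...]
    transport_ids: tuple[str, ...]
    internal_ids: tuple[str, ...]
    biomass_id: str

    @property
    def n_boundary(self) -> int:
        """Exchange plus transport count (the discarded predictor columns)."""
        return len(self.exchange_ids) + len(self.transport_ids)

    def all_ids(self) -> set[str]:
        return (
            set(self.exchange_ids)
            | set(self.transport_ids)
            | set(self.internal_ids)
            | {self.biomass_id}
        )


def _from_cobra(cobra_model) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(cobra_model, array_type="lil").tocsc()
    rxns = cobra_model.reactions
    return MetabolicModel(
        metabolite_ids=[m.id for m in cobra_model.metabolites],
        reaction_ids=[r.id for r in rxns],
        S=S,
        lower_bounds=np.array([r.lower_bound for r in rxns]),
        upper_bounds=np.array([r.upper_bound for r in rxns]),
        objective_coeffs=np.array([r.objective_coefficient for r in rxns]),
        subsystem=[r.subsystem or "" for r in rxns],
    )


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Read a constraint-based model from SBML or BiGG JSON.

    Parameters
    ----------
    path : file path
    format : {"sbml", "bigg_json"}, optional
        Inferred from the file extension when omitted (``.xml``/``.sbml`` vs
        ``.json``).

    Raises
    ------
    ModelFormatError
        If the file does not parse; no partial model is returned.
    ModelConfigurationError
        If the parsed model has no (or more than one) objective reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "bigg_json" if path.suffix.lower() == ".json" else "sbml"
    if format not in ("sbml", "bigg_json"):
        raise ValueError(f"unknown format {format!r}")

    import cobra.io

    try:
        if format == "bigg_json":
            cobra_model = cobra.io.load_json_model(str(path))
        else:
            cobra_model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises heterogeneous parse errors
        raise ModelFormatError(f"cannot parse {path.name} as {format}: {exc}") from exc

    model = _from_cobra(cobra_model)
    n_obj = int(np.count_nonzero(model.objective_coeffs))
    if n_obj == 0:
        raise ModelConfigurationError(f"{path.name}: no objective reaction defined")
    if n_obj > 1:
        ids = [model.reaction_ids[i] for i in np.flatnonzero(model.objective_coeffs)]
        raise ModelConfigurationError(
            f"{path.name}: multiple objective reactions: {ids}"
        )
    return model


def write_bigg_json(model: MetabolicModel, path: str | Path, model_id: str = "model") -> None:
    """Serialize a model as BiGG-schema JSON (readable by cobrapy)."""
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).tocoo()
        mets = {model.metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)}
        reactions.append(
            {
                "id": rid,
                "name": rid,
                "metabolites": mets,
                "lower_bound": float(model.lower_bounds[j]),
                "upper_bound": float(model.upper_bounds[j]),
                "gene_reaction_rule": "",
                "subsystem": model.subsystem[j],
                "objective_coefficient": float(model.objective_coeffs[j]),
            }
        )
    metabolites = []
    for mid in model.metabolite_ids:
        _, comp = model.split_species_compartment(mid)
        metabolites.append(
            {"id": mid, "name": mid, "compartment": comp or "c", "charge": 0, "formula": ""}
        )
    compartments = sorted({m["compartment"] for m in metabolites})
    doc = {
        "id": model_id,
        "version": "1",
        "metabolites": metabolites,
        "reactions": reactions,
        "genes": [],
        "compartments": {c: c for c in compartments},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _is_transport(model: MetabolicModel, j: int) -> bool:
    if "transport" in model.subsystem[j].lower():
        return True
    col = model.S.getcol(j).tocoo()
    species_comps: dict[str, set[str]] = {}
    for i in col.row:
        species, comp = model.split_species_compartment(model.metabolite_ids[i])
        species_comps.setdefault(species, set()).add(comp)
    return any(len(comps) > 1 for comps in species_comps.values())


def classify_reactions(model: MetabolicModel) -> ReactionPartition:
    """Partition reactions into exchange / transport / biomass / internal.

    Rules, applied in order of precedence:

    1. *biomass*: the unique reaction with nonzero objective coefficient
       (ambiguity is an error, never a guess);
    2. *exchange*: boundary pseudo-reactions touching exactly one metabolite
       (this covers BiGG ``EX_``/``DM_``/``SK_`` conventions);
    3. *transport*: subsystem annotation containing "transport"
       (case-insensitive) or stoichiometry moving the same chemical species
       between compartments;
    4. *internal*: everything else — the predictor features.
    """
    obj = np.flatnonzero(model.objective_coeffs)
    if obj.size == 0:
        raise ModelConfigurationError("model has no objective (biomass) reaction")
    if obj.size > 1:
        ids = [model.reaction_ids[i] for i in obj]
        raise ModelConfigurationError(f"multiple objective reactions: {ids}")
    biomass_id = model.reaction_ids[int(obj[0])]

    n_mets_per_rxn = np.diff(model.S.tocsc().indptr)
    exchange, transport, internal = [], [], []
    for j, rid in enumerate(model.reaction_ids):
        if rid == biomass_id:
            continue
        if n_mets_per_rxn[j] == 1:
            exchange.append(rid)
        elif _is_transport(model, j):
            transport.append(rid)
        else:
            internal.append(rid)
    if not internal:
        raise ModelConfigurationError(
            "degenerate model: no internal reactions left after classification"
        )
    return ReactionPartition(
        exchange_ids=tuple(exchange),
        transport_ids=tuple(transport),
        internal_ids=tuple(internal),
        biomass_id=biomass_id,
    )
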