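"""Growth environments: primary substrates, random impurities, uptake bounds.

An environment is a primary carbon source plus a primary nitrogen source (each
allowed uptake at the conventional 20 mmol gDW^-1 hr^-1), a set of randomly
sampled impurity substrates allowed uptake at 1/100 of that rate (chemical
noise in the medium), and an oxygen supply. Environments are applied to a
model purely by rewriting exchange-reaction lower bounds; the stoichiometry is
never touched.

Substrates are identified by their exchange-reaction ids throughout.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import MetabolicModel

__all__ = [
    "GrowthEnvironment",
    "SubstratePool",
    "load_substrate_pool",
    "sample_impurities",
    "apply_environment",
    "condition_grid",
    "PRIMARY_UPTAKE",
    "IMPURITY_UPTAKE",
    "OXYGEN_UPTAKE",
    "IAF1260_SEVEN_BY_SEVEN",
]

PRIMARY_UPTAKE = -20.0
IMPURITY_UPTAKE = -0.2  # 1/100 of the primary rate
OXYGEN_UPTAKE = -18.5
OXYGEN_EXCHANGE = "EX_o2_e"

#: the 7 carbon / 7 nitrogen primary substrates used for the reference study,
#: as BiGG exchange ids of iAF1260 (D-glucose ... D-sorbitol; ammonia ... L-glutamine)
IAF1260_SEVEN_BY_SEVEN = {
    "C": [
        "EX_glc__D_e",
        "EX_pyr_e",
        "EX_glyc_e",
        "EX_ac_e",
        "EX_rib__D_e",
        "EX_fru_e",
        "EX_sbt__D_e",
    ],
    "N": [
        "EX_nh4_e",
        "EX_ade_e",
        "EX_cytd_e",
        "EX_ptrc_e",
        "EX_gly_e",
        "EX_ala__L_e",
        "EX_gln__L_e",
    ],
}


@dataclass(frozen=True)
class GrowthEnvironment:
    """One composed medium: primaries, impurities, and uptake bounds."""

    carbon_source: str
    nitrogen_source: str
    impurities_C: tuple[str, ...] = ()
    impurities_N: tuple[str, ...] = ()
    primary_uptake: float = PRIMARY_UPTAKE
    impurity_uptake: float = IMPURITY_UPTAKE
    oxygen_uptake: float = OXYGEN_UPTAKE
    carbon_uptake: float | None = None  # override for excess-C scenarios
    nitrogen_uptake: float | None = None

    def __post_init__(self):
        primaries = {self.carbon_source, self.nitrogen_source}
        clash = primaries & (set(self.impurities_C) | set(self.impurities_N))
        if clash:
            raise ValueError(f"impurities coincide with primary sources: {sorted(clash)}")

    @property
    def effective_carbon_uptake(self) -> float:
        return self.primary_uptake if self.carbon_uptake is None else self.carbon_uptake

    @property
    def effective_nitrogen_uptake(self) -> float:
        return self.primary_uptake if self.nitrogen_uptake is None else self.nitrogen_uptake

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class SubstratePool:
    """Candidate carbon and nitrogen sources, as exchange-reaction ids."""

    carbon_pool: tuple[str, ...]
    nitrogen_pool: tuple[str, ...]

    def __post_init__(self):
        if not self.carbon_pool or not self.nitrogen_pool:
            raise ValueError("substrate pools must be non-empty")

    @property
    def all_exchanges(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.carbon_pool)
        seen.update(dict.fromkeys(self.nitrogen_pool))
        return tuple(seen)

    def validate_against(self, model: MetabolicModel) -> None:
        missing = [r for r in self.all_exchanges if r not in set(model.reaction_ids)]
        if missing:
            raise ValueError(f"pool substrates missing from model: {missing}")


def load_substrate_pool(path: str | Path) -> SubstratePool:
    """Read a two-column TSV (substrate id, role in {C, N}) into a pool.

    Bare BiGG metabolite ids (e.g. ``glc__D``) are mapped to their exchange
    reaction ``EX_glc__D_e``; ids already carrying the ``EX_`` prefix are kept.
    """
    carbon, nitrogen = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sub, role = parts[0].strip(), parts[1].strip().upper()
        rid = sub if sub.startswith("EX_") else f"EX_{sub}_e"
        if role == "C":
            carbon.append(rid)
        elif role == "N":
            nitrogen.append(rid)
        else:
            raise ValueError(f"{path}:{lineno}: role must be C or N, got {role!r}")
    return SubstratePool(carbon_pool=tuple(carbon), nitrogen_pool=tuple(nitrogen))


def sample_impurities(
    pool: SubstratePool,
    k_C: int,
    k_N: int,
    exclude: set[str] | tuple[str, ...] = (),
    rng: np.random.Generator | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Sample ``k_C`` carbon and ``k_N`` nitrogen impurities uniformly without
    replacement, never picking a primary source (``exclude``)."""
    rng = rng if rng is not None else np.random.default_rng()
    exclude = set(exclude)
    out = []
    for k, candidates in ((k_C, pool.carbon_pool), (k_N, pool.nitrogen_pool)):
        avail = [s for s in candidates if s not in exclude]
        if k > len(avail):
            raise ValueError(
                f"cannot sample {k} impurities from a pool of {len(avail)} "
                f"after excluding primaries"
            )
        picked = rng.choice(len(avail), size=k, replace=False) if k else []
        out.append(tuple(avail[int(i)] for i in picked))
    return out[0], out[1]


def apply_environment(
    model: MetabolicModel, env: GrowthEnvironment, pool: SubstratePool
) -> MetabolicModel:
    """Return a copy of ``model`` with exchange lower bounds set for ``env``.

    Every carbon/nitrogen exchange in ``pool`` is first closed (lb = 0), then
    the primaries and impurities are opened at their uptake rates; the oxygen
    exchange, when the model has one, is set to the configured uptake. All
    other bounds — ions, maintenance fluxes such as ATPM, internal reactions —
    are left exactly as encoded in the model.
    """
    known = set(model.reaction_ids)
    wanted = (
        {env.carbon_source, env.nitrogen_source}
        | set(env.impurities_C)
        | set(env.impurities_N)
    )
    missing = sorted(wanted - known)
    if missing:
        raise ValueError(f"substrates not in model: {missing}")
    pool.validate_against(model)

    out = model.copy()
    for rid in pool.all_exchanges:
        out.lower_bounds[out.reaction_index(rid)] = 0.0
    out.lower_bounds[out.reaction_index(env.carbon_source)] = env.effective_carbon_uptake
    out.lower_bounds[out.reaction_index(env.nitrogen_source)] = env.effective_nitrogen_uptake
    for rid in itertools.chain(env.impurities_C, env.impurities_N):
        out.lower_bounds[out.reaction_index(rid)] = env.impurity_uptake
    if OXYGEN_EXCHANGE in known:
        out.lower_bounds[out.reaction_index(OXYGEN_EXCHANGE)] = env.oxygen_uptake
    return out


def condition_grid(carbon_list, nitrogen_list) -> list[tuple[str, str]]:
    """All pairwise (carbon, nitrogen) combinations, in stable input order."""
    carbon_list, nitrogen_list = list(carbon_list), list(nitrogen_list)
    if not carbon_list or not nitrogen_list:
        raise ValueError("substrate lists must be non-empty")
    return list(itertools.product(carbon_list, nitrogen_list))
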