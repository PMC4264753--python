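"""Replicate FBA simulation across condition grids into labeled flux datasets.

One *observation* is a single FBA solve for a (carbon, nitrogen) condition with
a fresh draw of random impurities. The dataset keeps only internal-reaction
fluxes (exchange, transport, and biomass columns are removed — predicting the
environment from its own uptake fluxes would be trivial) together with the
condition labels, biomass values, and impurity provenance. Observations whose
biomass falls at or below the viability threshold are dropped, as are solver
failures, which are recorded with biomass 0 rather than aborting the batch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import fba
from .environments import (
    IMPURITY_UPTAKE,
    OXYGEN_UPTAKE,
    PRIMARY_UPTAKE,
    GrowthEnvironment,
    SubstratePool,
    sample_impurities,
)
from .model import MetabolicModel, ReactionPartition, classify_reactions

__all__ = ["SimulationConfig", "FluxDataset", "run_simulation", "split_train_test"]


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation batch."""

    conditions: list[tuple[str, str]]
    replicates: int = 100
    k_C: int = 1
    k_N: int = 1
    primary_uptake: float = PRIMARY_UPTAKE
    impurity_uptake: float = IMPURITY_UPTAKE
    oxygen_uptake: float = OXYGEN_UPTAKE
    carbon_uptake: float | None = None
    nitrogen_uptake: float | None = None
    viability_threshold: float = 0.558
    flux_min: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not math.isfinite(self.viability_threshold):
            raise ValueError("viability threshold must be finite")

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["conditions"] = [list(c) for c in self.conditions]
        return json.dumps(d, sort_keys=True)


@dataclass
class FluxDataset:
    """Observations x internal-reaction flux matrix with condition labels."""

    X: pd.DataFrame
    carbon_labels: pd.Series
    nitrogen_labels: pd.Series
    biomass: pd.Series
    replicate_id: pd.Series
    impurity_record: list[dict]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.X)
        for name in ("carbon_labels", "nitrogen_labels", "biomass", "replicate_id"):
            s = getattr(self, name)
            if len(s) != n:
                raise ValueError(f"{name} length {len(s)} != {n} observations")
        if len(self.impurity_record) != n:
            raise ValueError("impurity_record length mismatch")

    @property
    def n_obs(self) -> int:
        return len(self.X)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.X.columns)

    def joint_labels(self) -> pd.Series:
        return self.carbon_labels.str.cat(self.nitrogen_labels, sep="|")

    def subset(self, idx) -> "FluxDataset":
        idx = np.asarray(idx)
        return FluxDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            carbon_labels=self.carbon_labels.iloc[idx].reset_index(drop=True),
            nitrogen_labels=self.nitrogen_labels.iloc[idx].reset_index(drop=True),
            biomass=self.biomass.iloc[idx].reset_index(drop=True),
            replicate_id=self.replicate_id.iloc[idx].reset_index(drop=True),
            impurity_record=[self.impurity_record[int(i)] for i in idx],
            meta=dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        """Flat CSV: label/provenance columns then one column per reaction."""
        df = self.X.copy()
        df.insert(0, "carbon_source", self.carbon_labels)
        df.insert(1, "nitrogen_source", self.nitrogen_labels)
        df.insert(2, "biomass", self.biomass)
        df.insert(3, "replicate_id", self.replicate_id)
        df.insert(4, "impurities", [json.dumps(r, sort_keys=True) for r in self.impurity_record])
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FluxDataset":
        df = pd.read_csv(path)
        label_cols = ["carbon_source", "nitrogen_source", "biomass", "replicate_id", "impurities"]
        return cls(
            X=df.drop(columns=label_cols),
            carbon_labels=df["carbon_source"],
            nitrogen_labels=df["nitrogen_source"],
            biomass=df["biomass"],
            replicate_id=df["replicate_id"],
            impurity_record=[json.loads(s) for s in df["impurities"]],
        )


def run_simulation(
    model: MetabolicModel,
    pool: SubstratePool,
    config: SimulationConfig,
    partition: ReactionPartition | None = None,
) -> FluxDataset:
    """Run ``replicates`` FBA solves per condition and assemble the dataset.

    Each replicate samples fresh impurities (the only source of randomness),
    applies the environment, maximizes biomass, and — when ``config.flux_min``
    is set — canonicalizes the optimum by minimizing total absolute flux at
    fixed biomass. Non-viable observations (solver failure or biomass at or
    below the threshold) are counted in ``meta`` and excluded.
    """
    from .environments import apply_environment

    if partition is None:
        partition = classify_reactions(model)
    internal = list(partition.internal_ids)
    internal_idx = np.array([model.reaction_index(r) for r in internal])
    rng = np.random.default_rng(config.seed)

    rows, carbons, nitrogens, biomasses, reps, impurities = [], [], [], [], [], []
    n_total = 0
    n_dropped = 0
    dropped_by_condition: dict[str, int] = {}
    for c_src, n_src in config.conditions:
        for rep in range(config.replicates):
            n_total += 1
            imp_C, imp_N = sample_impurities(
                pool, config.k_C, config.k_N, exclude={c_src, n_src}, rng=rng
            )
            env = GrowthEnvironment(
                carbon_source=c_src,
                nitrogen_source=n_src,
                impurities_C=imp_C,
                impurities_N=imp_N,
                primary_uptake=config.primary_uptake,
                impurity_uptake=config.impurity_uptake,
                oxygen_uptake=config.oxygen_uptake,
                carbon_uptake=config.carbon_uptake,
                nitrogen_uptake=config.nitrogen_uptake,
            )
            bounded = apply_environment(model, env, pool)
            sol = fba.solve_fba(bounded)
            if sol.optimal and config.flux_min:
                sol = fba.minimize_total_flux(bounded, sol.biomass)
            biomass = sol.biomass if sol.optimal else 0.0
            if not sol.optimal or biomass <= config.viability_threshold:
                n_dropped += 1
                key = f"{c_src}|{n_src}"
                dropped_by_condition[key] = dropped_by_condition.get(key, 0) + 1
                continue
            rows.append(sol.fluxes[internal_idx])
            carbons.append(c_src)
            nitrogens.append(n_src)
            biomasses.append(biomass)
            reps.append(rep)
            impurities.append({"C": list(imp_C), "N": list(imp_N)})

    X = pd.DataFrame(np.array(rows) if rows else np.empty((0, len(internal))), columns=internal)
    return FluxDataset(
        X=X,
        carbon_labels=pd.Series(carbons, dtype=str),
        nitrogen_labels=pd.Series(nitrogens, dtype=str),
        biomass=pd.Series(biomasses, dtype=float),
        replicate_id=pd.Series(reps, dtype=int),
        impurity_record=impurities,
        meta={
            "n_total": n_total,
            "n_viable": len(rows),
            "n_dropped": n_dropped,
            "dropped_by_condition": dropped_by_condition,
            "config": json.loads(config.to_json()),
        },
    )


def split_train_test(
    dataset: FluxDataset,
    test_fraction: float = 0.5,
    train_size: int | None = None,
    seed: int = 0,
) -> tuple[FluxDataset, FluxDataset]:
    """Split into train and test, stratified by (carbon, nitrogen) condition.

    ``ceil(test_fraction * n)`` observations go to the test set; when
    ``train_size`` is given, the training set is further subsampled (again
    stratified) to that size.
    """
    n = dataset.n_obs
    n_test = math.ceil(test_fraction * n)
    strata = dataset.joint_labels().to_numpy()
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, stratify=strata, random_state=seed
    )
    if train_size is not None:
        if train_size > len(train_idx):
            raise ValueError(
                f"train_size {train_size} exceeds available {len(train_idx)} observations"
            )
        if train_size < len(train_idx):
            train_idx, _ = train_test_split(
                train_idx,
                train_size=train_size,
                stratify=strata[train_idx],
                random_state=seed,
            )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))
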