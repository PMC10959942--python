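"""Pedigree simulation and the planted ground truth container."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..pedigree import MISSING, PED_COLUMNS, Pedigree

#: Named, order-stable random substreams; every generator stage draws from
#: its own stream so adding draws in one stage never perturbs another.
_STREAMS = ("genome", "pedigree", "snv", "cnv", "prs")


def substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class GroundTruth:
    """Planted events, one entry per event, each in exactly one category.

    ``de_novo`` rows: variant_id, child_id, bin, quality_fail, fail_mode.
    ``inherited`` rows: variant_id, child_id, origin (paternal/maternal).
    ``cnv_events`` rows: event_id, sample_id, chrom, start, end, cnv_type,
    origin, size_class (large/rgd/typical).
    ``biallelic`` / ``xlinked``: planted recessive events.
    """

    de_novo: list[dict] = field(default_factory=list)
    inherited: list[dict] = field(default_factory=list)
    cnv_events: list[dict] = field(default_factory=list)
    biallelic: list[dict] = field(default_factory=list)
    xlinked: list[dict] = field(default_factory=list)
    prs_meta: dict = field(default_factory=dict)

    @property
    def true_de_novo_ids(self) -> set[tuple[str, str]]:
        return {(d["variant_id"], d["child_id"]) for d in self.de_novo}

    def passing_de_novo_ids(self) -> set[tuple[str, str]]:
        return {
            (d["variant_id"], d["child_id"])
            for d in self.de_novo
            if not d["quality_fail"]
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_novo": self.de_novo,
            "inherited": self.inherited,
            "cnv_events": self.cnv_events,
            "biallelic": self.biallelic,
            "xlinked": self.xlinked,
            "prs_meta": self.prs_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def generate_pedigrees(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Simulate nuclear families: parents plus affected/unaffected children.

    A multiplex (MPX) family carries two (occasionally three) affected
    children; a simplex (SPX) family carries one. Unaffected sibling count
    is Poisson with mean ``sibling_rate``. Sexes of affected children are
    male with probability ``p_affected_male`` (emulating the ~3.2:1 male
    excess of ASD cohorts); unaffected siblings are male with probability
    one half.
    """
    if rng is None:
        rng = substreams(config.seed)["pedigree"]
    rows: list[dict] = []
    for i in range(config.n_families):
        fid = f"F{i + 1:03d}"
        father = f"{fid}.1"
        mother = f"{fid}.2"
        rows.append(dict(fid=fid, iid=father, father=MISSING, mother=MISSING, sex=1, phenotype=1))
        rows.append(dict(fid=fid, iid=mother, father=MISSING, mother=MISSING, sex=2, phenotype=1))
        multiplex = rng.random() < config.fraction_multiplex
        n_affected = 1
        if multiplex:
            n_affected = 3 if rng.random() < 0.1 else 2
        n_unaffected = int(rng.poisson(config.sibling_rate))
        child_no = 3
        for _ in range(n_affected):
            sex = 1 if rng.random() < config.p_affected_male else 2
            rows.append(
                dict(fid=fid, iid=f"{fid}.{child_no}", father=father, mother=mother, sex=sex, phenotype=2)
            )
            child_no += 1
        for _ in range(n_unaffected):
            sex = 1 if rng.random() < 0.5 else 2
            rows.append(
                dict(fid=fid, iid=f"{fid}.{child_no}", father=father, mother=mother, sex=sex, phenotype=1)
            )
            child_no += 1
    table = pd.DataFrame(rows, columns=PED_COLUMNS)
    if config.missing_parent_families:
        # remove the mother's DNA from the first k families (she stays in
        # the household but has no genotype data): children point at "0".
        fids = table["fid"].unique()[: config.missing_parent_families]
        for fid in fids:
            mother = f"{fid}.2"
            table = table[table["iid"] != mother]
            table.loc[(table["fid"] == fid) & (table["mother"] == mother), "mother"] = MISSING
    return Pedigree(table.reset_index(drop=True))
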