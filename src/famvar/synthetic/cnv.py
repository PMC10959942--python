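"""Multi-caller CNV call-set simulation with planted ground truth.

True copy-number events (deletions/duplications) are planted per family:
inherited events sit in one parent and are transmitted to each child with
probability one half; de novo events appear only in a child. Every carrier
individual is then "observed" by three emulated array callers (the first,
``arrayA``, acts as the required primary caller) with Gaussian boundary
jitter, per-caller dropout and occasional low-confidence calls, and — for
families with genome sequencing — by one emulated read-depth WGS caller
with tight boundaries. Single-caller noise calls are sprinkled in to
exercise the consensus filter.

Events are placed on genes away from centromeres, segmental duplications
and copy-number-unstable windows, so that with zero dropout every planted
event >= 10 kb with >= 5 probes survives the stringent rare-CNV filter.
A polymorphic common deletion region (carried by ~8% of parents) exercises
the parental-frequency filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import SimulationConfig
from ..pedigree import Individual, Pedigree
from .cohort import GroundTruth
from .genome import AUTOSOMES, CHROM_LENGTH, RGD_LOCI, SyntheticGenome

ARRAY_CALLERS = ("arrayA", "arrayB", "arrayC")
PRIMARY_CALLER = "arrayA"
WGS_CALLER = "wgs"

CALL_COLUMNS = [
    "sample_id", "fid", "chrom", "start", "end", "cnv_type",
    "caller", "confidence", "n_probes", "platform",
]

#: windows (relative to any chromosome) that event placement must avoid
_BAD_WINDOWS = ((4_500_000, 5_700_000), (28_800_000, 31_200_000), (44_500_000, 45_650_000), (47_500_000, 49_500_000))

_COMMON_REGION = ("chr1", 16_000_000, 16_040_000)  # polymorphic common deletion


def _clean_gene_pool(genome: SyntheticGenome) -> pd.DataFrame:
    g = genome.genes
    g = g[g["chrom"].isin(AUTOSOMES)]
    bad = np.zeros(len(g), dtype=bool)
    for s, e in _BAD_WINDOWS:
        bad |= (g["start"] < e + 500_000) & (g["end"] > s - 500_000)
    for chrom, s, e in RGD_LOCI:
        bad |= (g["chrom"] == chrom) & (g["start"] < e + 500_000) & (g["end"] > s - 500_000)
    bad |= (g["chrom"] == _COMMON_REGION[0]) & (g["start"] < _COMMON_REGION[2] + 500_000) & (
        g["end"] > _COMMON_REGION[1] - 500_000
    )
    return g[~bad]


class _EventPlacer:
    """Draws event intervals; 'typical' events take genes without
    replacement cohort-wide so private events stay private (parental
    cohort frequency below the 1% rarity cut), mirroring truly rare CNVs.
    Large (>= 3 Mb) events are de novo only: probands with large inherited
    CNVs would have been excluded by prior clinical array screening."""

    def __init__(self, rng: np.random.Generator, pool: pd.DataFrame):
        self.rng = rng
        self.order = list(rng.permutation(len(pool)))
        self.pool = pool
        self.cursor = 0

    def _next_gene(self):
        if self.cursor >= len(self.order):  # recycle if the pool runs dry
            self.order = list(self.rng.permutation(len(self.pool)))
            self.cursor = 0
        row = self.pool.iloc[self.order[self.cursor]]
        self.cursor += 1
        return row

    def draw(self, allow_large: bool) -> tuple[str, int, int, str]:
        rng = self.rng
        u = rng.random()
        if u < 0.05:
            chrom, ls, le = RGD_LOCI[int(rng.integers(0, len(RGD_LOCI)))]
            length = le - ls
            start = ls + int(rng.uniform(0, 0.2) * length)
            end = le - int(rng.uniform(0, 0.2) * length)
            return chrom, start, end, "rgd"
        if allow_large and u < 0.10:
            chrom = "chr1" if rng.random() < 0.5 else "chr6"
            size = int(rng.uniform(3_000_000, 4_000_000))
            start = int(rng.uniform(6_000_000, 22_000_000))
            return chrom, start, start + size, "large"
        row = self._next_gene()
        size = int(np.exp(rng.uniform(np.log(15_000), np.log(300_000))))
        start = int(row.start - rng.uniform(0, size / 2))
        end = start + size
        end = min(end, CHROM_LENGTH)
        return str(row.chrom), max(0, start), end, "typical"


def _emit_calls(
    rng: np.random.Generator,
    genome: SyntheticGenome,
    config: SimulationConfig,
    person: Individual,
    chrom: str,
    start: int,
    end: int,
    cnv_type: str,
    has_wgs: bool,
    rows: list[dict],
) -> None:
    for caller in ARRAY_CALLERS:
        if rng.random() < config.cnv_dropout:
            continue
        sd = config.cnv_boundary_jitter_sd
        js = start + int(rng.normal(0, sd))
        je = end + int(rng.normal(0, sd))
        if je <= js:  # truncate the jitter so the interval stays proper
            js, je = start, end
        js = max(0, js)
        low_conf = config.cnv_dropout > 0 and rng.random() < config.cnv_dropout
        conf = float(np.round(rng.uniform(2.0, 9.5) if low_conf else rng.uniform(12.0, 80.0), 1))
        rows.append(
            dict(
                sample_id=person.iid, fid=person.fid, chrom=chrom, start=js, end=je,
                cnv_type=cnv_type, caller=caller, confidence=conf,
                n_probes=genome.n_probes(js, je), platform="array",
            )
        )
    if has_wgs and (end - start) >= 10_000:
        js = start + int(rng.normal(0, 50.0))
        je = end + int(rng.normal(0, 50.0))
        if je <= js:
            js, je = start, end
        rows.append(
            dict(
                sample_id=person.iid, fid=person.fid, chrom=chrom, start=max(0, js), end=je,
                cnv_type=cnv_type, caller=WGS_CALLER, confidence=float(np.round(rng.uniform(20, 99), 1)),
                n_probes=0, platform="wgs",
            )
        )


def generate_cnv_callsets(
    pedigree: Pedigree,
    config: SimulationConfig,
    genome: SyntheticGenome,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth, set[str]]:
    """Simulate per-caller CNV call tables.

    Returns (call table, ground truth, set of family ids with WGS data).
    """
    if config.cnv_boundary_jitter_sd < 0:
        raise ValueError("boundary jitter sd must be non-negative")
    if truth is None:
        truth = GroundTruth()
    placer = _EventPlacer(rng, _clean_gene_pool(genome))
    rows: list[dict] = []
    event_no = 0
    families = pedigree.families
    n_wgs = int(round(config.wgs_family_fraction * len(families)))
    wgs_fids = {f.fid for f in families[:n_wgs]}

    def record_truth(event_id, person, chrom, start, end, cnv_type, origin, size_class, rare=True):
        truth.cnv_events.append(
            dict(
                event_id=event_id, sample_id=person.iid, fid=person.fid, chrom=chrom,
                start=start, end=end, cnv_type=cnv_type, origin=origin,
                size_class=size_class, rare=rare,
            )
        )

    for fam in families:
        has_wgs = fam.fid in wgs_fids
        father = next((p for p in fam.parents if p.is_male), None)
        mother = next((p for p in fam.parents if not p.is_male), None)
        fam_rgd_chroms: set[str] = set()

        def draw_event(allow_large: bool) -> tuple[str, int, int, str]:
            # one RGD event per locus per family, so inheritance stays
            # unambiguous (each locus lies on its own chromosome)
            for _ in range(5):
                chrom, start, end, size_class = placer.draw(allow_large)
                if size_class != "rgd" or chrom not in fam_rgd_chroms:
                    if size_class == "rgd":
                        fam_rgd_chroms.add(chrom)
                    return chrom, start, end, size_class
            return placer.draw(False)

        # inherited events
        for _ in range(int(rng.poisson(config.inherited_cnvs_per_family))):
            chrom, start, end, size_class = draw_event(allow_large=False)
            cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
            carrier = father if rng.random() < 0.5 else mother
            if carrier is None:
                carrier = father or mother
            event_no += 1
            eid = f"cnv{event_no:04d}"
            origin = "paternal" if carrier.is_male else "maternal"
            _emit_calls(rng, genome, config, carrier, chrom, start, end, cnv_type, has_wgs, rows)
            record_truth(eid, carrier, chrom, start, end, cnv_type, "founder", size_class)
            for child in fam.children:
                if rng.random() < 0.5:
                    _emit_calls(rng, genome, config, child, chrom, start, end, cnv_type, has_wgs, rows)
                    record_truth(eid, child, chrom, start, end, cnv_type, origin, size_class)

        # de novo events in children
        for child in fam.children:
            for _ in range(int(rng.poisson(config.de_novo_cnv_rate_per_child))):
                chrom, start, end, size_class = draw_event(allow_large=True)
                cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
                event_no += 1
                eid = f"cnv{event_no:04d}"
                _emit_calls(rng, genome, config, child, chrom, start, end, cnv_type, has_wgs, rows)
                record_truth(eid, child, chrom, start, end, cnv_type, "de_novo", size_class)

        # common polymorphic deletion (filtered by parental frequency)
        chrom, cs, ce = _COMMON_REGION
        for parent in (father, mother):
            if parent is not None and rng.random() < 0.08:
                event_no += 1
                eid = f"cnv{event_no:04d}"
                _emit_calls(rng, genome, config, parent, chrom, cs, ce, "DEL", has_wgs, rows)
                record_truth(eid, parent, chrom, cs, ce, "DEL", "founder", "common", rare=False)
                origin = "paternal" if parent.is_male else "maternal"
                for child in fam.children:
                    if rng.random() < 0.5:
                        _emit_calls(rng, genome, config, child, chrom, cs, ce, "DEL", has_wgs, rows)
                        record_truth(eid, child, chrom, cs, ce, "DEL", origin, "common", rare=False)

        # single-caller noise calls (rejected by the consensus rule)
        for person in fam.members:
            for _ in range(int(rng.poisson(0.5))):
                chrom = str(rng.choice(AUTOSOMES))
                start = int(rng.uniform(1_000_000, CHROM_LENGTH - 1_000_000))
                size = int(rng.uniform(2_000, 8_000))
                caller = str(rng.choice(ARRAY_CALLERS))
                rows.append(
                    dict(
                        sample_id=person.iid, fid=person.fid, chrom=chrom, start=start,
                        end=start + size, cnv_type="DEL" if rng.random() < 0.5 else "DUP",
                        caller=caller, confidence=float(np.round(rng.uniform(10, 40), 1)),
                        n_probes=genome.n_probes(start, start + size), platform="array",
                    )
                )

    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return calls, truth, wgs_fids
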