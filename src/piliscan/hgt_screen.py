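"""Dynamic-percentile screening for horizontally transferred genes.

Per genome, each gene's metric value is compared against the values of all
*other* genes of the same genome (leave-one-out): GC content, RSCU
deviation and ENC flag a gene when its value exceeds the 90th percentile of
the others; CAI flags when the value falls below the 10th percentile.

The percentile is the nearest-rank-above empirical quantile
(``numpy.percentile(..., method="higher")``) with a strict inequality at
the threshold.  This keeps the screen calibrated: on tie-free values at
most ``ceil(0.1 * N)`` genes can carry any one flag.  Undefined (``nan``)
metrics never raise a flag and are excluded from comparison sets.

A gene is called HGT when at least ``k`` of the four flags are set
(default 3 of 4).  Per-family acquisition rates summarize calls across a
genome cohort.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .codon_metrics import CodonProfile

HIGH_METRICS = ("gc", "rscu_dev", "enc")   # flagged above the 90th percentile
LOW_METRICS = ("cai",)                     # flagged below the 10th percentile


@dataclass
class HGTCall:
    gene_id: str
    flag_gc: bool = False
    flag_rscu: bool = False
    flag_enc: bool = False
    flag_cai: bool = False
    is_hgt: bool = False

    @property
    def n_flags(self) -> int:
        return sum((self.flag_gc, self.flag_rscu, self.flag_enc,
                    self.flag_cai))


@dataclass
class AcquisitionRate:
    family_name: str
    n_genomes_with_family: int
    n_flagged: int

    @property
    def rate(self) -> float:
        return self.n_flagged / self.n_genomes_with_family


def _loo_flag(values: np.ndarray, idx: int, q: float, high: bool) -> bool:
    others = np.delete(values, idx)
    others = others[~np.isnan(others)]
    if others.size == 0 or math.isnan(values[idx]):
        return False
    threshold = float(np.percentile(others, q, method="higher" if high
                                    else "lower"))
    return values[idx] > threshold if high else values[idx] < threshold


def percentile_flags(profiles: list[CodonProfile],
                     min_profiles: int = 20) -> list[HGTCall]:
    """Leave-one-out percentile flags for every profiled gene of a genome."""
    if len(profiles) < min_profiles:
        raise ValueError(
            f"need >= {min_profiles} profiles for meaningful percentiles, "
            f"got {len(profiles)}"
        )
    arrays = {
        m: np.array([getattr(p, m) for p in profiles], dtype=float)
        for m in HIGH_METRICS + LOW_METRICS
    }
    calls = []
    for i, p in enumerate(profiles):
        calls.append(HGTCall(
            gene_id=p.gene_id,
            flag_gc=_loo_flag(arrays["gc"], i, 90, high=True),
            flag_rscu=_loo_flag(arrays["rscu_dev"], i, 90, high=True),
            flag_enc=_loo_flag(arrays["enc"], i, 90, high=True),
            flag_cai=_loo_flag(arrays["cai"], i, 10, high=False),
        ))
    return calls


def composite_call(calls: list[HGTCall], k: int = 3) -> list[HGTCall]:
    """Set ``is_hgt`` on each call: at least ``k`` of the four flags."""
    if k not in (1, 2, 3, 4):
        raise ValueError("k must be in 1..4")
    for c in calls:
        c.is_hgt = c.n_flags >= k
    return calls


def acquisition_rates(
    calls_by_genome: dict[str, list[HGTCall]],
    family_by_gene: dict[str, dict[str, str]],
) -> list[AcquisitionRate]:
    """Per-family HGT acquisition rates across a genome cohort.

    ``family_by_gene`` maps genome_id -> {gene_id -> family_name} (the
    assignments produced by the locus scan).  A family counts as flagged in
    a genome when any of its member genes there is called HGT; families
    present in zero genomes are omitted.
    """
    present: Counter[str] = Counter()
    flagged: Counter[str] = Counter()
    for genome_id, assignments in family_by_gene.items():
        call_by_id = {c.gene_id: c for c in calls_by_genome.get(genome_id, [])}
        fams = set(assignments.values())
        for fam in fams:
            present[fam] += 1
            if any(call_by_id[gid].is_hgt
                   for gid, f in assignments.items()
                   if f == fam and gid in call_by_id):
                flagged[fam] += 1
    return [
        AcquisitionRate(family_name=fam,
                        n_genomes_with_family=present[fam],
                        n_flagged=flagged[fam])
        for fam in sorted(present)
    ]
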