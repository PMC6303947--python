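"""Aggregation of enzyme-kinetics measurements.

Each record is one enzyme-substrate-cofactor measurement carrying kcat
(1/s), KM (uM; K_1/2 allowed with a flag) and/or catalytic efficiency
kcat/KM (1/(M s)).  The module derives missing quantities, determines
each enzyme's best (most efficient) substrate, and computes the
family-level summary statistics (medians over best-substrate records,
pair and compound counts).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace

import numpy as np

#: relative tolerance of the kcat / KM / efficiency unit-consistency check
CONSISTENCY_RTOL = 0.05


@dataclass(frozen=True)
class KineticRecord:
    enzyme_id: str
    substrate: str
    subfamily: str | None = None
    cofactor: str = "unknown"
    kcat: float | None = None  # 1/s
    km_uM: float | None = None  # uM (or K_1/2 when k_half is set)
    efficiency: float | None = None  # kcat/KM in 1/(M s)
    k_half: bool = False
    best: bool = False
    inconsistent: bool = False
    source: str | None = None

    def __post_init__(self) -> None:
        for name in ("kcat", "km_uM", "efficiency"):
            val = getattr(self, name)
            if val is not None and (not math.isfinite(val) or val <= 0):
                raise ValueError(f"{self.enzyme_id}/{self.substrate}: {name} must be positive, got {val}")


def derive_efficiency(record: KineticRecord) -> KineticRecord:
    """Fill in the missing one of {kcat, KM, efficiency} from the other two.

    When all three are present they are checked for unit consistency
    (efficiency = kcat / (KM * 1e-6) within 5%); inconsistent records are
    flagged but the reported efficiency is kept.  Idempotent.
    """
    kcat, km, eff = record.kcat, record.km_uM, record.efficiency
    if kcat is not None and km is not None and eff is not None:
        implied = kcat / (km * 1e-6)
        if abs(implied - eff) > CONSISTENCY_RTOL * eff:
            return replace(record, inconsistent=True)
        return record
    if kcat is not None and km is not None:
        return replace(record, efficiency=kcat / (km * 1e-6))
    if eff is not None and km is not None:
        return replace(record, kcat=eff * km * 1e-6)
    if eff is not None and kcat is not None:
        return replace(record, km_uM=kcat / eff * 1e6)
    return record


def dedup_records(records: list[KineticRecord]) -> list[KineticRecord]:
    """Drop duplicate (enzyme, substrate, cofactor, source) rows.

    Conflicting duplicates keep the highest-efficiency row (missing
    efficiency ranks lowest).
    """
    best: dict[tuple, KineticRecord] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec.enzyme_id, rec.substrate, rec.cofactor, rec.source)
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            old = best[key].efficiency or -math.inf
            new = rec.efficiency or -math.inf
            if new > old:
                best[key] = rec
    return [best[k] for k in order]


def best_substrates(records: list[KineticRecord]) -> tuple[list[KineticRecord], list[str]]:
    """Flag, per enzyme, the substrate with maximal catalytic efficiency.

    Ties are broken by smaller KM, then alphabetically by substrate.
    Returns the flagged records plus the list of enzymes with no
    efficiency value at all (excluded from the best-substrate analysis).
    """
    records = [derive_efficiency(r) for r in records]
    by_enzyme: dict[str, list[KineticRecord]] = defaultdict(list)
    for rec in records:
        by_enzyme[rec.enzyme_id].append(rec)
    excluded = []
    winners: dict[int, bool] = {}
    for enzyme, recs in by_enzyme.items():
        with_eff = [r for r in recs if r.efficiency is not None]
        if not with_eff:
            excluded.append(enzyme)
            continue
        best = min(
            with_eff,
            key=lambda r: (-r.efficiency, r.km_uM if r.km_uM is not None else math.inf, r.substrate),
        )
        winners[id(best)] = True
    out = [replace(r, best=(id(r) in winners)) for r in records]
    return out, sorted(excluded)


def family_summary(records: list[KineticRecord]) -> dict:
    """Family-level kinetics summary.

    Computes medians of efficiency and KM over best-substrate records,
    the number of enzyme-substrate pairs with a determined catalytic
    efficiency, the number of distinct accepted compounds (any measured
    activity) and of distinct best compounds, plus per-subfamily medians.
    Medians of even-sized sets are the mean of the central pair.
    """
    if not records:
        raise ValueError("no kinetic records supplied")
    records = dedup_records([derive_efficiency(r) for r in records])
    flagged, excluded = best_substrates(records)
    best = [r for r in flagged if r.best]
    best_eff = [r.efficiency for r in best if r.efficiency is not None]
    best_km = [r.km_uM for r in best if r.km_uM is not None]
    pairs = {(r.enzyme_id, r.substrate) for r in flagged if r.efficiency is not None}
    per_subfamily = {}
    by_sf: dict[str, list[KineticRecord]] = defaultdict(list)
    for rec in best:
        by_sf[rec.subfamily or "unknown"].append(rec)
    for sf in sorted(by_sf):
        recs = by_sf[sf]
        effs = [r.efficiency for r in recs if r.efficiency is not None]
        kms = [r.km_uM for r in recs if r.km_uM is not None]
        per_subfamily[sf] = {
            "n_enzymes": len(recs),
            "median_best_efficiency": float(np.median(effs)) if effs else None,
            "median_best_km_uM": float(np.median(kms)) if kms else None,
        }
    return {
        "median_best_efficiency": float(np.median(best_eff)) if best_eff else None,
        "median_best_km_uM": float(np.median(best_km)) if best_km else None,
        "n_pairs_with_efficiency": len(pairs),
        "n_accepted_compounds": len({r.substrate for r in flagged}),
        "n_best_compounds": len({r.substrate for r in best}),
        "n_enzymes_without_efficiency": len(excluded),
        "enzymes_without_efficiency": excluded,
        "per_subfamily": per_subfamily,
    }
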