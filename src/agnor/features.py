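"""Per-nucleus summaries and case-level AgNOR parameters.

The case-level vector mirrors the classical AgNOR morphometry menu:

============  ===============================================================
nornbc_m      mean conglomerate-corrected AgNOR count per nucleus
nor_k0..k8    percentage of nuclei containing exactly k AgNORs (corrected)
snar_r_v      mean over nuclei of the within-nucleus SD of per-mille
              single-particle area fractions (area_i / total area x 1000)
mnrat2_m      mean over nuclei of the largest/total AgNOR area ratio, per mille
cent_r_v      SD across nuclei of the proportion of particles in the central
              zone (d_norm <= central cutoff)
bord_r_v      SD across nuclei of the proportion in the peripheral zone
              (d_norm >= peripheral cutoff)
center_v      SD of d_norm over all centrally located particles, pooled
locat_v       variance of d_norm over all particles, pooled across nuclei
============  ===============================================================

Nuclei without particles contribute a zero count (hence to ``nor_k0`` and to
``nornbc_m``) but are excluded from the area and zone aggregates, whose
values are undefined for them. Per-mille quantities stay unrounded here;
rounding happens only in reports. Population SDs (ddof=0) are used
throughout so that single-particle and single-nucleus cases are well
defined and identical inputs give exactly zero spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import AgNORParticle, NucleusRecord

__all__ = [
    "ZoneDefinition",
    "NucleusFeatureRow",
    "CaseFeatures",
    "nucleus_features",
    "case_features",
    "features_from_records",
    "records_from_ground_truth",
    "feature_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = [
    "nornbc_m",
    "nor_k0", "nor_k1", "nor_k2", "nor_k3", "nor_k4",
    "nor_k5", "nor_k6", "nor_k7", "nor_k8",
    "snar_r_v", "center_v", "cent_r_v", "bord_r_v", "locat_v", "mnrat2_m",
]


@dataclass(frozen=True)
class ZoneDefinition:
    """Nuclear zones on the normalised radial coordinate.

    Central means ``d_norm <= central_cutoff``; peripheral means
    ``d_norm >= peripheral_cutoff``. Defaults (0.5, 0.8) split the nucleus
    into an inner half-radius core and an outer rim.
    """

    central_cutoff: float = 0.5
    peripheral_cutoff: float = 0.8

    def __post_init__(self):
        if not 0.0 < self.central_cutoff < self.peripheral_cutoff < 1.0:
            raise ValueError("zones require 0 < central_cutoff < peripheral_cutoff < 1")


@dataclass
class NucleusFeatureRow:
    nucleus_id: int
    corrected_count: int
    raw_count: int
    area_fractions_pm: np.ndarray  # per-mille fractions, one per particle
    fraction_sd_pm: float  # NaN when no particles
    largest_total_pm: float  # NaN when no particles
    central_proportion: float  # NaN when no particles
    peripheral_proportion: float  # NaN when no particles
    d_norms: np.ndarray = field(default_factory=lambda: np.empty(0))


def nucleus_features(record: NucleusRecord, zones: ZoneDefinition | None = None) -> NucleusFeatureRow:
    """Within-nucleus AgNOR summaries for one marked nucleus."""
    zones = zones or ZoneDefinition()
    areas = np.array([p.area_um2 for p in record.particles], dtype=float)
    d = np.array([p.d_norm for p in record.particles], dtype=float)
    count = record.corrected_count
    if areas.size == 0:
        return NucleusFeatureRow(
            nucleus_id=record.nucleus_id,
            corrected_count=0,
            raw_count=0,
            area_fractions_pm=np.empty(0),
            fraction_sd_pm=np.nan,
            largest_total_pm=np.nan,
            central_proportion=np.nan,
            peripheral_proportion=np.nan,
            d_norms=d,
        )
    fractions = areas / areas.sum() * 1000.0
    return NucleusFeatureRow(
        nucleus_id=record.nucleus_id,
        corrected_count=count,
        raw_count=record.raw_count,
        area_fractions_pm=fractions,
        fraction_sd_pm=float(np.std(fractions)),
        largest_total_pm=float(fractions.max()),
        central_proportion=float(np.mean(d <= zones.central_cutoff)),
        peripheral_proportion=float(np.mean(d >= zones.peripheral_cutoff)),
        d_norms=d,
    )


@dataclass
class CaseFeatures:
    """The case-level AgNOR parameter vector."""

    nornbc_m: float
    count_percentages: dict[int, float]  # percentage of nuclei per corrected count
    snar_r_v: float
    center_v: float
    cent_r_v: float
    bord_r_v: float
    locat_v: float
    mnrat2_m: float
    n_nuclei: int = 0

    def nor_k(self, k: int) -> float:
        return self.count_percentages.get(k, 0.0)

    def to_series(self) -> pd.Series:
        values = {"nornbc_m": self.nornbc_m}
        for k in range(9):
            values[f"nor_k{k}"] = self.nor_k(k)
        values.update(
            snar_r_v=self.snar_r_v,
            center_v=self.center_v,
            cent_r_v=self.cent_r_v,
            bord_r_v=self.bord_r_v,
            locat_v=self.locat_v,
            mnrat2_m=self.mnrat2_m,
        )
        return pd.Series(values, index=FEATURE_COLUMNS)


def case_features(
    rows: list[NucleusFeatureRow],
    zones: ZoneDefinition | None = None,
) -> CaseFeatures:
    """Aggregate per-nucleus rows into the case-level parameter vector.

    ``cent_r_v`` / ``bord_r_v`` are spreads of the zone proportions *across*
    nuclei; ``snar_r_v`` averages the *within*-nucleus spread of area
    fractions; ``center_v`` and ``locat_v`` pool particles across nuclei.
    """
    if not rows:
        raise ValueError("need at least one nucleus")
    zones = zones or ZoneDefinition()
    n = len(rows)
    counts = np.array([r.corrected_count for r in rows], dtype=float)
    uniq, freq = np.unique(counts.astype(int), return_counts=True)
    pct = {int(k): 100.0 * c / n for k, c in zip(uniq, freq)}

    nonempty = [r for r in rows if r.raw_count > 0]
    if nonempty:
        snar = float(np.mean([r.fraction_sd_pm for r in nonempty]))
        mnrat = float(np.mean([r.largest_total_pm for r in nonempty]))
        cent_r = float(np.std([r.central_proportion for r in nonempty]))
        bord_r = float(np.std([r.peripheral_proportion for r in nonempty]))
        pooled = np.concatenate([r.d_norms for r in nonempty])
        locat = float(np.var(pooled))
        central = pooled[pooled <= zones.central_cutoff]
        center = float(np.std(central)) if central.size else np.nan
    else:
        snar = mnrat = cent_r = bord_r = locat = center = np.nan

    return CaseFeatures(
        nornbc_m=float(counts.mean()),
        count_percentages=pct,
        snar_r_v=snar,
        center_v=center,
        cent_r_v=cent_r,
        bord_r_v=bord_r,
        locat_v=locat,
        mnrat2_m=mnrat,
        n_nuclei=n,
    )


def features_from_records(
    records: list[NucleusRecord], zones: ZoneDefinition | None = None
) -> CaseFeatures:
    """Detection output -> case feature vector in one call."""
    zones = zones or ZoneDefinition()
    return case_features([nucleus_features(r, zones) for r in records], zones)


def records_from_ground_truth(
    particles: pd.DataFrame,
    nuclei: pd.DataFrame,
    case_id: int = 0,
) -> list[NucleusRecord]:
    """Build NucleusRecords from generator ground truth.

    Conglomerate members are merged into a single particle (as a detector
    sees them): the area is the member total, the centroid and d_norm are
    area-weighted member averages, and the corrected count is the true
    member multiplicity. Useful as the truth-side input of pipeline
    recovery checks.
    """
    nuc = nuclei[nuclei["case_id"] == case_id]
    par = particles[particles["case_id"] == case_id]
    records = []
    for _, nrow in nuc.iterrows():
        nid = int(nrow["nucleus_id"])
        sub = par[par["nucleus_id"] == nid]
        plist: list[AgNORParticle] = []
        for _, grp in sub.groupby("conglomerate_group"):
            areas = grp["area_um2"].to_numpy(dtype=float)
            w = areas / areas.sum()
            m = len(grp)
            plist.append(
                AgNORParticle(
                    area_um2=float(areas.sum()),
                    centroid_um=(
                        float(np.dot(w, grp["y_um"])),
                        float(np.dot(w, grp["x_um"])),
                    ),
                    d_norm=float(np.dot(w, grp["d_norm"])),
                    is_conglomerate=m > 1,
                    corrected_count=m if m > 1 else 1,
                )
            )
        plist.sort(key=lambda p: (-p.area_um2, p.centroid_um[0], p.centroid_um[1]))
        a, b = float(nrow["semi_major_um"]), float(nrow["semi_minor_um"])
        records.append(
            NucleusRecord(
                nucleus_id=nid,
                area_um2=np.pi * a * b,
                centroid_um=(float(nrow["centroid_y_um"]), float(nrow["centroid_x_um"])),
                particles=plist,
            )
        )
    return records


def feature_table(case_records: dict, zones: ZoneDefinition | None = None) -> pd.DataFrame:
    """Case id -> records mapping to a one-row-per-case feature table."""
    rows = {}
    for cid, records in case_records.items():
        rows[cid] = features_from_records(records, zones).to_series()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "case_id"
    return out.reset_index()
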