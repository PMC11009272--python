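"""Relative and absolute abundance profiles, redox zonation, and NOB composition.

The absolute-abundance convention follows the standard qPCR-scaled amplicon
recipe: a group's cells per gram = (archaeal + bacterial 16S copies per gram)
x (the group's relative amplicon abundance). No 16S copy-number correction is
applied. Depth averaging integrates trapezoidally over the sampled span only
— never extrapolating to the sediment surface or to the oxygen penetration
depth — and divides by that span.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .guilds import GuildMap, NOB_LINEAGES
from .tables import GeochemProfile, OtuTable, SampleTable


@dataclasses.dataclass
class AbundanceMatrix:
    """Samples x groups abundance values; ``kind`` is 'relative' or 'absolute'."""

    values: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "absolute"):
            raise ParameterError(f"kind must be 'relative' or 'absolute', got {self.kind!r}")
        if (self.values.values < 0).any():
            raise ParameterError("abundance values must be non-negative")
        if self.kind == "relative" and (self.values.sum(axis=1) > 1 + 1e-9).any():
            raise ParameterError("relative abundances exceed 1 in at least one sample")


@dataclasses.dataclass
class OpdEstimate:
    """Oxygen penetration depth; ``bounded`` is False when O2 never crossed the
    threshold and the bottom sampled depth was returned instead."""

    core_id: str
    opd_cm: float
    bounded: bool = True


@dataclasses.dataclass
class RedoxZones:
    """Per-sample oxic/anoxic labels. The boundary is closed: depth == OPD is oxic."""

    data: pd.DataFrame  # columns: sample_id, core_id, depth_cm, zone
    opd_cm: dict[str, float]

    def sample_ids(self, zone: str) -> list[str]:
        return list(self.data.loc[self.data["zone"] == zone, "sample_id"])


def relative_abundances(otu_table: OtuTable, guilds: GuildMap) -> AbundanceMatrix:
    """Per-sample relative abundance of each guild (sum of member OTU fractions).

    Every OTU in the table must be covered by the guild map (possibly as
    'other'); guild fractions per sample therefore sum to 1.
    """
    missing = [otu for otu in otu_table.otu_ids if otu not in guilds.labels]
    if missing:
        raise ParameterError(
            f"guild map does not cover OTUs: {', '.join(map(str, missing[:5]))}"
            + ("..." if len(missing) > 5 else "")
        )
    totals = otu_table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ParameterError(f"sample {zero[0]!r} has zero total counts")
    fractions = otu_table.counts.div(totals, axis=0)
    labels = pd.Series({otu: guilds.labels[otu] for otu in otu_table.otu_ids})
    grouped = fractions.T.groupby(labels).sum().T
    return AbundanceMatrix(values=grouped, kind="relative")


def absolute_abundances(rel: AbundanceMatrix, samples: SampleTable) -> AbundanceMatrix:
    """Scale relative abundances to cells per gram with the qPCR totals."""
    if rel.kind != "relative":
        raise ParameterError("absolute_abundances expects a relative AbundanceMatrix")
    totals = samples.total_cells()
    missing = [s for s in rel.values.index if s not in totals.index]
    if missing:
        raise ParameterError(f"sample {missing[0]!r} has no qPCR values")
    totals = totals.reindex(rel.values.index)
    if totals.isna().any():
        bad = totals.index[totals.isna()][0]
        raise ParameterError(f"sample {bad!r} has missing qPCR values")
    return AbundanceMatrix(values=rel.values.mul(totals, axis=0), kind="absolute")


def infer_opd(profile: GeochemProfile, threshold_uM: float = 1.0) -> OpdEstimate:
    """Oxygen penetration depth: the shallowest depth where linearly
    interpolated O2 crosses ``threshold_uM``.

    If O2 stays above the threshold over the whole profile the bottom depth is
    returned flagged ``bounded=False``. Measured OPD values, when available,
    should be preferred over this inference.
    """
    if profile.o2_uM is None:
        raise ParameterError(
            f"core {profile.core_id!r} has no O2 series; supply the OPD directly"
        )
    finite = np.isfinite(profile.o2_uM)
    depth = profile.depth_cm[finite]
    o2 = profile.o2_uM[finite]
    if len(o2) < 2:
        raise ParameterError(f"core {profile.core_id!r}: need >=2 finite O2 points")
    if o2[0] <= threshold_uM:
        raise ParameterError(
            f"core {profile.core_id!r}: surface O2 {o2[0]:g} uM is already at or "
            f"below the threshold {threshold_uM:g} uM"
        )
    for k in range(len(o2) - 1):
        if o2[k] > threshold_uM >= o2[k + 1]:
            frac = (o2[k] - threshold_uM) / (o2[k] - o2[k + 1])
            return OpdEstimate(
                core_id=profile.core_id,
                opd_cm=float(depth[k] + frac * (depth[k + 1] - depth[k])),
            )
    return OpdEstimate(core_id=profile.core_id, opd_cm=float(depth[-1]), bounded=False)


def split_redox_zones(
    samples: SampleTable, opd_by_core: Mapping[str, float]
) -> RedoxZones:
    """Label every sample oxic (depth <= OPD of its core) or anoxic."""
    rows = []
    for _, row in samples.data.iterrows():
        core = str(row["core_id"])
        if core not in opd_by_core:
            raise ParameterError(f"no OPD known for core {core!r}")
        depth = float(row["depth_cm"])
        rows.append(
            dict(sample_id=row["sample_id"], core_id=core, depth_cm=depth,
                 zone="oxic" if depth <= opd_by_core[core] else "anoxic")
        )
    return RedoxZones(data=pd.DataFrame(rows), opd_cm=dict(opd_by_core))


def depth_averaged_abundance(
    values: Sequence[float],
    depths: Sequence[float],
    zone_bounds: tuple[float, float] | None = None,
    allow_single: bool = False,
) -> float:
    """Trapezoidal depth average: integral of value vs depth over the sampled
    span inside ``zone_bounds`` (inclusive), divided by that span."""
    values = np.asarray(values, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if values.shape != depths.shape:
        raise ParameterError("values and depths must have equal length")
    if not np.all(np.diff(depths) > 0):
        raise ParameterError("depths must be strictly increasing")
    if zone_bounds is not None:
        lo, hi = zone_bounds
        mask = (depths >= lo) & (depths <= hi)
        values, depths = values[mask], depths[mask]
    if len(values) < 2:
        if len(values) == 1 and allow_single:
            return float(values[0])
        raise ParameterError(
            "need >=2 in-zone samples for a depth average "
            "(pass allow_single=True for single-sample passthrough)"
        )
    span = depths[-1] - depths[0]
    return float(np.trapezoid(values, depths) / span)


@dataclasses.dataclass
class NobComposition:
    """Lineage fractions within the NOB guild, per sample and depth-averaged per core."""

    per_sample: pd.DataFrame    # samples x NOB lineages, rows sum to 1
    depth_averaged: pd.DataFrame  # cores x NOB lineages
    excluded_samples: list[str]


def nob_composition(
    absolute: AbundanceMatrix,
    samples: SampleTable,
    zones: RedoxZones | None = None,
    allow_single: bool = True,
) -> NobComposition:
    """Fractions of the canonical families and the candidate lineage among
    total NOB, per sample and depth-averaged per core (oxic samples only when
    ``zones`` is given). Samples with zero total NOB are excluded with a
    warning."""
    lineages = [c for c in NOB_LINEAGES if c in absolute.values.columns]
    if not lineages:
        raise ParameterError("abundance matrix has no NOB lineage columns")
    sub = absolute.values[lineages]
    if zones is not None:
        keep = [s for s in sub.index if s in set(zones.sample_ids("oxic"))]
        sub = sub.loc[keep]
    totals = sub.sum(axis=1)
    excluded = list(totals.index[totals == 0])
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) with zero total NOB excluded from composition"
        )
    sub = sub.loc[totals > 0]
    fractions = sub.div(sub.sum(axis=1), axis=0)

    depths = samples.depths()
    cores = samples.cores()
    rows = {}
    for core_id in sorted(cores.unique()):
        ids = [s for s in fractions.index if cores[s] == core_id]
        if not ids:
            continue
        ids = sorted(ids, key=lambda s: depths[s])
        z = depths[ids].to_numpy()
        rows[core_id] = {
            lin: depth_averaged_abundance(
                fractions.loc[ids, lin].to_numpy(), z, allow_single=allow_single
            )
            for lin in lineages
        }
    return NobComposition(
        per_sample=fractions,
        depth_averaged=pd.DataFrame.from_dict(rows, orient="index")[lineages]
        if rows else pd.DataFrame(columns=lineages),
        excluded_samples=excluded,
    )
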