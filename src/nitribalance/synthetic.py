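"""Synthetic sediment-core generator.

Emulates the data structure of a multi-core nitrifier survey: depth-resolved
amplicon counts, per-sample qPCR totals (archaeal + bacterial 16S copies per
gram), porewater oxygen profiles, and a truth table of the underlying guild
abundances. Inside the oxic zone the true cell ratio of ammonia-oxidizing
archaea (AOA) to the *combined* nitrite-oxidizing bacteria (NOB: two
canonical families plus a candidate lineage) is held at ``r_true``; the
candidate lineage carries a fraction ``f_candidate`` of all NOB cells, so
excluding it inflates every oxic-zone ratio by exactly ``1/(1-f_candidate)``.

Abundances decline exponentially with depth (rate ``decay_per_cm``). Below
the oxygen penetration depth (OPD) the aerobes (AOA and the canonical NOB
families) decay steeply toward zero, while the candidate lineage persists at
a constant floor fraction of its value at the OPD — an illustrative, not
mechanistic, rendering of an anaerotolerant nitrite oxidizer.

Randomness: one root seed is split with ``numpy.random.SeedSequence`` into a
community stream (background OTU abundances) plus one stream per core, so
adding a core never perturbs earlier cores.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tables import (
    GeochemProfile,
    OtuTable,
    SampleTable,
    Taxonomy,
    write_geochem,
    write_otu_table,
    write_sample_table,
    write_taxonomy,
)

# Fixed OTU roster of the nitrifier guilds. Within-guild splits are constants
# of the generator: they shape per-OTU counts but cancel in every guild-level
# statistic.
AOA_OTUS: tuple[tuple[str, float], ...] = (("OTU_1", 0.8), ("OTU_2", 0.2))
NITROSPIRACEAE_OTU = "OTU_3"
NITROSPINACEAE_OTU = "OTU_5"
CANDIDATE_OTUS: tuple[tuple[str, float], ...] = (
    ("OTU_4", 0.6),
    ("OTU_235", 0.3),
    ("OTU_57", 0.1),
)
ANAMMOX_OTU = "OTU_8"
DECOY_CANDIDATE_OTU = "OTU_99"  # same phylum label, deliberately unverified

_LINEAGES = {
    "AOA": ("Archaea", "Crenarchaeota", "Nitrososphaeria", "Nitrosopumilales",
            "Nitrosopumilaceae", "Nitrosopumilus"),
    "Nitrospiraceae": ("Bacteria", "Nitrospirota", "Nitrospiria", "Nitrospirales",
                       "Nitrospiraceae", "Nitrospira"),
    "Nitrospinaceae": ("Bacteria", "Nitrospinota", "Nitrospinia", "Nitrospinales",
                       "Nitrospinaceae", "Nitrospina"),
    "candidate": ("Bacteria", "Schekmanbacteria", "unclassified", "unclassified",
                  "unclassified", "unclassified"),
    "anammox": ("Bacteria", "Planctomycetota", "Brocadiae", "Brocadiales",
                "Brocadiaceae", "Candidatus_Scalindua"),
}

_BACKGROUND_FAMILIES = (
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Xanthomonadales",
     "Woeseiaceae", "Woeseia"),
    ("Bacteria", "Chloroflexota", "Dehalococcoidia", "SAR202", "unclassified",
     "unclassified"),
    ("Bacteria", "Planctomycetota", "Phycisphaerae", "MSBL9", "unclassified",
     "unclassified"),
    ("Bacteria", "Acidobacteriota", "Thermoanaerobaculia", "Aminicenantales",
     "unclassified", "unclassified"),
    ("Archaea", "Thermoplasmatota", "Thermoplasmata", "Marine_Group_II",
     "unclassified", "unclassified"),
    ("Bacteria", "Gemmatimonadota", "Gemmatimonadetes", "Gemmatimonadales",
     "Gemmatimonadaceae", "unclassified"),
)

_COUNT_MODELS = ("multinomial", "expected")


@dataclasses.dataclass
class SyntheticParams:
    """All knobs of the simulated survey. Defaults are the package's standard
    study conditions: 10 cores, 10 oxic + 2 anoxic depths each (100 oxic
    samples), a true oxic-zone AOA:NOB ratio of 10 with the candidate lineage
    carrying 65% of NOB cells, 30,000 reads per sample, and 0.3 lognormal
    sigma on the qPCR totals."""

    n_cores: int = 10
    depths_cm: Sequence[float] = (2, 6, 10, 14, 18, 22, 26, 30, 34, 38, 44, 50)
    opd_cm: float | Sequence[float] = 40.0
    o2_surface_uM: float = 250.0
    r_true: float = 10.0
    f_candidate: float = 0.65
    f_split_canonical: float = 0.5
    aoa_surface_cells: float = 1e7
    decay_per_cm: float = 0.05
    background_otus: int = 30
    background_mean_cells: float = 3e6
    background_lognorm_sigma: float = 1.0
    read_depth: int = 30000
    qpcr_sigma: float = 0.3
    anoxic_decay_per_cm: float = 0.5
    candidate_anoxic_floor: float = 0.5
    count_model: str = "multinomial"
    seed: int = 1

    def opd_for_core(self, index: int) -> float:
        if np.isscalar(self.opd_cm):
            return float(self.opd_cm)  # type: ignore[arg-type]
        return float(self.opd_cm[index])  # type: ignore[index]

    def validate(self) -> None:
        if self.n_cores < 1:
            raise ParameterError("n_cores must be >= 1")
        depths = np.asarray(self.depths_cm, dtype=float)
        if depths.ndim != 1 or len(depths) < 1 or not np.all(np.diff(depths) > 0):
            raise ParameterError("depths_cm must be a strictly increasing sequence")
        if depths[0] < 0:
            raise ParameterError("depths_cm must be non-negative")
        opds = [self.opd_for_core(i) for i in range(self.n_cores)]
        if any(o <= 0 for o in opds):
            raise ParameterError("opd_cm must be positive")
        if self.o2_surface_uM <= 0:
            raise ParameterError("o2_surface_uM must be positive")
        if self.r_true <= 0:
            raise ParameterError("r_true must be positive")
        if not 0 <= self.f_candidate < 1:
            raise ParameterError("f_candidate must be in [0, 1)")
        if not 0 <= self.f_split_canonical <= 1:
            raise ParameterError("f_split_canonical must be in [0, 1]")
        if self.aoa_surface_cells <= 0:
            raise ParameterError("aoa_surface_cells must be positive")
        if self.decay_per_cm < 0:
            raise ParameterError("decay_per_cm must be non-negative")
        if self.background_otus < 0:
            raise ParameterError("background_otus must be non-negative")
        if self.background_mean_cells <= 0:
            raise ParameterError("background_mean_cells must be positive")
        if self.background_lognorm_sigma < 0:
            raise ParameterError("background_lognorm_sigma must be non-negative")
        if self.read_depth < 1:
            raise ParameterError("read_depth must be >= 1")
        if self.qpcr_sigma < 0:
            raise ParameterError("qpcr_sigma must be non-negative")
        if self.anoxic_decay_per_cm < 0:
            raise ParameterError("anoxic_decay_per_cm must be non-negative")
        if not 0 <= self.candidate_anoxic_floor <= 1:
            raise ParameterError("candidate_anoxic_floor must be in [0, 1]")
        if self.count_model not in _COUNT_MODELS:
            raise ParameterError(
                f"count_model must be one of {_COUNT_MODELS}, got {self.count_model!r}"
            )


@dataclasses.dataclass
class SyntheticDataset:
    """A generated survey plus the ground truth behind it."""

    otu_table: OtuTable
    taxonomy: Taxonomy
    samples: SampleTable
    geochem: dict[str, GeochemProfile]
    truth: pd.DataFrame
    verified_candidate_otus: tuple[str, ...]
    params: SyntheticParams


def make_o2_profile(
    depths_cm: Sequence[float],
    opd_cm: float,
    o2_surface_uM: float,
    core_id: str = "core",
) -> GeochemProfile:
    """Linear-to-zero oxygen profile: ``o2_surface`` at 0 cm, 0 at the OPD and below."""
    if opd_cm <= 0:
        raise ParameterError("opd_cm must be positive")
    depths = np.asarray(depths_cm, dtype=float)
    o2 = o2_surface_uM * np.clip(1.0 - depths / opd_cm, 0.0, None)
    return GeochemProfile(core_id=core_id, depth_cm=depths, o2_uM=o2)


def draw_amplicon_counts(
    rel_abund: Sequence[float], read_depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One multinomial amplicon observation; counts sum to ``read_depth`` exactly."""
    rel = np.asarray(rel_abund, dtype=float)
    if (rel < 0).any():
        raise ParameterError("rel_abund contains a negative probability")
    if abs(rel.sum() - 1.0) > 1e-9:
        raise ParameterError(f"rel_abund sums to {rel.sum()!r}, expected 1")
    if read_depth < 1:
        raise ParameterError("read_depth must be >= 1")
    return rng.multinomial(read_depth, rel / rel.sum())


def expected_counts(rel_abund: Sequence[float], read_depth: int) -> np.ndarray:
    """Deterministic counts: expected values under the multinomial, rounded by
    largest remainder so they sum to ``read_depth`` exactly. Expected counts
    within 1e-6 of an integer are snapped to it first, so communities whose
    expected counts are integral are reproduced without quantization."""
    rel = np.asarray(rel_abund, dtype=float)
    if (rel < 0).any():
        raise ParameterError("rel_abund contains a negative probability")
    expect = rel / rel.sum() * read_depth
    expect = np.where(np.abs(expect - np.rint(expect)) < 1e-6, np.rint(expect), expect)
    base = np.floor(expect).astype(np.int64)
    short = int(read_depth - base.sum())
    if short > 0:
        order = np.argsort(-(expect - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:  # only reachable when snapping rounded several cells up
        order = np.argsort(expect - base, kind="stable")
        base[order[: -short]] -= 1
    return base


def _otu_roster(params: SyntheticParams) -> tuple[list[str], Taxonomy]:
    otus: list[str] = [otu for otu, _ in AOA_OTUS]
    lineages: dict[str, tuple[str, ...]] = {o: _LINEAGES["AOA"] for o in otus}
    otus += [NITROSPIRACEAE_OTU, NITROSPINACEAE_OTU]
    lineages[NITROSPIRACEAE_OTU] = _LINEAGES["Nitrospiraceae"]
    lineages[NITROSPINACEAE_OTU] = _LINEAGES["Nitrospinaceae"]
    for otu, _ in CANDIDATE_OTUS:
        otus.append(otu)
        lineages[otu] = _LINEAGES["candidate"]
    if params.background_otus > 0:
        otus.append(ANAMMOX_OTU)
        lineages[ANAMMOX_OTU] = _LINEAGES["anammox"]
        otus.append(DECOY_CANDIDATE_OTU)
        lineages[DECOY_CANDIDATE_OTU] = _LINEAGES["candidate"]
        for k in range(params.background_otus):
            otu = f"OTU_{100 + k}"
            otus.append(otu)
            lineages[otu] = _BACKGROUND_FAMILIES[k % len(_BACKGROUND_FAMILIES)]
    return otus, Taxonomy(lineages, database="synthetic taxonomy")


def _geochem_for_core(core_id: str, params: SyntheticParams, opd: float) -> GeochemProfile:
    depths = np.asarray(params.depths_cm, dtype=float)
    if depths[0] > 0:
        depths = np.concatenate([[0.0], depths])
    profile = make_o2_profile(depths, opd, params.o2_surface_uM, core_id=core_id)
    # crude but plausible companion profiles: nitrate accumulates in the oxic
    # zone and is drawn down below it; ammonium appears only below the OPD
    no3 = np.where(
        depths <= opd,
        15.0 + 10.0 * depths / opd,
        np.clip(25.0 * (1.0 - (depths - opd) / (2.0 * opd)), 0.0, None),
    )
    nh4 = np.where(depths <= opd, 0.0, 2.0 * (depths - opd) / opd)
    no2 = np.full_like(depths, 0.05)
    profile.no3_uM = no3
    profile.no2_uM = no2
    profile.nh4_uM = nh4
    return profile


def generate_dataset(params: SyntheticParams) -> SyntheticDataset:
    """Generate one synthetic survey. Deterministic given ``params.seed``."""
    params.validate()
    otus, taxonomy = _otu_roster(params)
    n_otus = len(otus)
    col = {otu: i for i, otu in enumerate(otus)}

    root = np.random.SeedSequence(params.seed)
    community_seed, *core_seeds = root.spawn(1 + params.n_cores)
    community_rng = np.random.default_rng(community_seed)
    bg_medians = params.background_mean_cells * np.exp(
        params.background_lognorm_sigma * community_rng.standard_normal(params.background_otus)
    )

    count_rows: list[np.ndarray] = []
    sample_rows: list[dict] = []
    truth_rows: list[dict] = []
    geochem: dict[str, GeochemProfile] = {}

    for ci in range(params.n_cores):
        core_id = f"C{ci + 1:02d}"
        opd = params.opd_for_core(ci)
        rng = np.random.default_rng(core_seeds[ci])
        geochem[core_id] = _geochem_for_core(core_id, params, opd)
        cand_at_opd = (
            params.f_candidate
            * params.aoa_surface_cells
            * np.exp(-params.decay_per_cm * opd)
            / params.r_true
        )
        for depth in np.asarray(params.depths_cm, dtype=float):
            oxic = depth <= opd
            base = params.aoa_surface_cells * np.exp(-params.decay_per_cm * depth)
            extra = 1.0 if oxic else np.exp(-params.anoxic_decay_per_cm * (depth - opd))
            aoa = base * extra
            nob_oxic = base / params.r_true
            if oxic:
                cand = params.f_candidate * nob_oxic
            else:
                cand = params.candidate_anoxic_floor * cand_at_opd
            canon = (1.0 - params.f_candidate) * nob_oxic * extra
            spira = params.f_split_canonical * canon
            spina = (1.0 - params.f_split_canonical) * canon

            ab = np.zeros(n_otus)
            for otu, w in AOA_OTUS:
                ab[col[otu]] = w * aoa
            ab[col[NITROSPIRACEAE_OTU]] = spira
            ab[col[NITROSPINACEAE_OTU]] = spina
            for otu, w in CANDIDATE_OTUS:
                ab[col[otu]] = w * cand
            background_total = 0.0
            anammox = 0.0
            if params.background_otus > 0:
                anammox = 0.02 * params.background_mean_cells * (0.05 if oxic else 1.0)
                ab[col[ANAMMOX_OTU]] = anammox
                ab[col[DECOY_CANDIDATE_OTU]] = (
                    0.01 * params.background_mean_cells * np.exp(-params.decay_per_cm * depth)
                )
                bg = bg_medians * np.exp(-params.decay_per_cm * depth)
                for k in range(params.background_otus):
                    ab[col[f"OTU_{100 + k}"]] = bg[k]
                background_total = ab[col[DECOY_CANDIDATE_OTU]] + bg.sum()

            total = ab.sum()
            rel = ab / total
            if params.count_model == "multinomial":
                counts = draw_amplicon_counts(rel, params.read_depth, rng)
            else:
                counts = expected_counts(rel, params.read_depth)
            count_rows.append(counts)

            noise = np.exp(params.qpcr_sigma * rng.standard_normal(2))
            qpcr_arch = aoa * noise[0]
            qpcr_bac = (total - aoa) * noise[1]

            sample_id = f"{core_id}-{depth:g}cm"
            sample_rows.append(
                dict(sample_id=sample_id, core_id=core_id, depth_cm=depth,
                     qpcr_arch=qpcr_arch, qpcr_bac=qpcr_bac)
            )
            nob_total = spira + spina + cand
            truth_rows.append(
                dict(sample_id=sample_id, core_id=core_id, depth_cm=depth,
                     zone="oxic" if oxic else "anoxic",
                     aoa=aoa, nob_nitrospiraceae=spira, nob_nitrospinaceae=spina,
                     nob_candidate=cand, nob_total=nob_total, anammox=anammox,
                     background=background_total, total_cells=total,
                     ratio_true=aoa / nob_total)
            )

    counts = pd.DataFrame(
        np.vstack(count_rows),
        index=pd.Index([row["sample_id"] for row in sample_rows]),
        columns=pd.Index(otus),
    )
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    return SyntheticDataset(
        otu_table=OtuTable(counts),
        taxonomy=taxonomy,
        samples=SampleTable(pd.DataFrame(sample_rows)),
        geochem=geochem,
        truth=truth,
        verified_candidate_otus=tuple(otu for otu, _ in CANDIDATE_OTUS),
        params=params,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset as the TSV bundle the readers consume, plus the truth table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "otu_counts": out / "otu_counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "samples": out / "samples.tsv",
        "geochem": out / "geochem.tsv",
        "truth": out / "truth.tsv",
        "candidates": out / "candidates.txt",
    }
    write_otu_table(dataset.otu_table, paths["otu_counts"])
    write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    write_sample_table(dataset.samples, paths["samples"])
    write_geochem(dataset.geochem, paths["geochem"])
    dataset.truth.to_csv(paths["truth"], sep="\t")
    paths["candidates"].write_text(
        "".join(f"{otu}\n" for otu in dataset.verified_candidate_otus)
    )
    return paths
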