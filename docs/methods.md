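# Methods

## The abundance-balance argument

Nitrification in oxic sediments couples two chemolithoautotrophic guilds:
ammonia-oxidizing archaea (AOA) produce nitrite, nitrite-oxidizing bacteria
(NOB) consume it. Where nitrite does not accumulate, the two bulk rates are
equal, so the standing stocks of the guilds are set by how much biomass each
builds per mole of nitrogen oxidized (yield, Y) and how much carbon one cell
contains (quota, Q):

```
N_AOA / N_NOB = (Y_AOA / Y_NOB) / (Q_AOA / Q_NOB)
```

With marine isolate traits — yield ratio 1.6–3.1 (mean 2.3), quota ratio
0.20–0.63 (mean 0.30) — the expected cell ratio band is low = 1.6/0.63,
central = 2.3/0.30, high = 3.1/0.20, i.e. (2.540, 7.667, 15.500). The
published band for the same traits is (2.6, 6.9, 15.8); it is not exactly
reproducible from the printed rounded traits, presumably because it was
derived from unrounded values. The package therefore offers two band modes —
`published` (the default, used as the reference band for exceedance counts)
and `computed` — and flags the discrepancy in reports whenever the computed
mode is used. The band logic assumes balanced rates and is meaningful only in
well-oxygenated, nitrite-poor settings; all ratio statistics are therefore
restricted to oxic-zone samples.

Observed ratios use absolute abundances reconstructed exactly as such surveys
operationalize them: a guild's cells g⁻¹ = (archaeal + bacterial 16S copies
g⁻¹ by qPCR) × (the guild's relative amplicon abundance). No 16S copy-number
correction is applied; the qPCR "copies per gram" unit is carried opaquely
(wet vs dry mass is a property of the input data, not of this package).
Note one useful consequence: qPCR noise multiplies both guilds of a sample
equally and cancels from every per-sample ratio, so ratio statistics are
sensitive only to the amplicon counting noise.

## The reattribution comparison

The question "does a candidate lineage resolve an apparent AOA excess" is
answered by running the identical ratio statistics twice on the same oxic
sample set: once with NOB = Nitrospiraceae + Nitrospinaceae (canonical
families), once adding the candidate lineage. If the candidate carries a
fraction f of all NOB cells, excluding it multiplies every per-sample ratio —
and hence the median, a monotone statistic — by exactly 1/(1−f). Samples with
zero canonical NOB are excluded from the ratio statistics of *both* arms (so
the arms stay paired) but retained in the regressions, where a zero abundance
is a legitimate point; this asymmetry is deliberate and reported.

Statistics follow the conventions of the field's abundance compilations:

- **Regression**: ordinary least squares of AOA on NOB on raw, untransformed
  abundances (statsmodels), reported both with an intercept (default) and
  through the origin, since figure conventions vary; slope and R² for each.
- **Median CI**: percentile bootstrap of the median, default 10,000 seeded
  resamples at level 0.99. The method is stated in output (`ci_method`)
  because "99% confidence interval of the median" alone underdetermines it.
- **Band exceedance**: counts strictly above band.high / strictly below
  band.low.
- The mean per-sample ratio and the regression slope are both reported: the
  two are often conflated in figure captions and need not agree.

## The synthetic generator

`SyntheticParams` describes a multi-core survey; its defaults are the
package's standard study conditions (10 cores × 12 depths of which 10 are
oxic, OPD 40 cm, r_true = 10, f_candidate = 0.65, read_depth = 30,000,
qpcr_sigma = 0.3), giving 100 oxic samples.

Per core, true abundances (cells g⁻¹) follow:

- AOA: `aoa_surface_cells · exp(−decay_per_cm · z)` in the oxic zone
  (default 1e7 at the surface, decay 0.05 cm⁻¹ — a simple monotone form with
  closed-form integrals, chosen because real profiles decline but follow no
  stated functional law).
- Total NOB in the oxic zone: AOA / r_true, split as f_candidate to the
  candidate lineage and the remainder between the two canonical families
  (f_split_canonical, default 0.5).
- Below the OPD, the aerobes (AOA and canonical NOB) take an extra decay
  `exp(−anoxic_decay_per_cm · (z − OPD))`; the candidate persists at a
  constant floor, `candidate_anoxic_floor ×` its value at the OPD. The floor
  is an illustrative rendering of an anaerotolerant lineage, not a
  mechanistic model — no quantitative anoxic model is available to emulate.
- A background community of `background_otus` non-nitrifier OTUs with
  lognormal abundance dispersion (σ = 1.0 around a 3e6 cells g⁻¹ median),
  plus one anammox OTU (elevated below the OPD) and one unverified
  "decoy" OTU sharing the candidate's phylum label — these exist only when
  the background is on, so that background-free runs have exactly the
  nitrifier community and support exact arithmetic.

Observation model: per-sample relative abundances are observed as one
multinomial draw of `read_depth` reads (counts always sum to the read depth);
qPCR totals get multiplicative lognormal noise `exp(σ·N(0,1))` with σ =
`qpcr_sigma` (median-unbiased; the noise model is a package choice, stated
rather than inherited). Oxygen profiles are linear from `o2_surface_uM` at
0 cm to zero at the OPD — again the simplest shape consistent with measured
curves. Companion nitrate/nitrite/ammonium series are plausible furniture
only.

Seeding: the root seed is split via `numpy.random.SeedSequence` into one
community stream plus one stream per core, so appending a core leaves all
earlier cores bit-identical.

What the generator does **not** emulate: compositional correlations among
background taxa, depth-varying community evenness, primer/copy-number bias,
chimeras, or any reaction-transport control of the geochemistry. Passing
tests therefore demonstrate the correctness of the estimators under the
stated observation model, not robustness to every artifact of real amplicon
data.

### Exactness and the `expected` count model

A multinomial draw at finite read depth quantizes relative abundances, so a
"zero-noise" run through the full count pipeline can only reproduce planted
ratios exactly when the expected per-OTU counts are integers. The generator
therefore has `count_model="expected"`: counts are the multinomial
expectations rounded by largest remainder (with values within 1e-6 of an
integer snapped first). Exactness tests use background-free communities with
rational compositions (e.g. r_true = 3, read_depth = 32,000), where every
expected count is integral and the inflation law
`median_without / median_with = 1/(1−f_candidate)` holds to machine
precision through counts → relative → absolute → ratios. With noise enabled,
recovery is statistical and is verified to 10% at the default study size.

## Depth profiles and zonation

- **OPD inference**: shallowest depth where linearly interpolated O2 crosses
  a threshold (default 1 µM — a measurement-floor convention, since survey
  reports state measured OPDs without a cutoff). A measured OPD, when
  supplied, always overrides inference. If O2 never crosses, the bottom
  sampled depth is returned flagged `bounded=False`.
- **Zonation**: oxic iff depth ≤ OPD (closed boundary; the tie rule is one
  line and documented here).
- **Depth averaging**: trapezoidal integral over the sampled span inside the
  zone divided by that span — no extrapolation to the sediment surface or to
  the OPD, which would invent unsampled data. Fewer than two in-zone samples
  is an error unless single-sample passthrough is explicitly allowed (NOB
  composition allows it by default, since sparse cores are common).

## Guild assignment and sequence identity

Guild patterns are case-insensitive exact name matches at a stated rank;
an OTU matching two guilds is a hard error, never a silent priority, so the
output cannot depend on pattern order. Candidate-lineage membership is
special: database classifications of the lineage are unstable across
reference releases, so membership comes only from an explicit verified OTU
list; OTUs with the candidate-looking phylum that are not on the list go to
`other` (with a provenance note saying why).

Percent identity uses a semi-global (overlap) alignment: match +1, mismatch
−1, linear gap −2, free terminal gaps; identity = matches / aligned columns
with terminal gap columns excluded, so a 220-bp amplicon against a 1,565-bp
gene is scored over the overlap. Co-optimal alignments are resolved by a
fixed traceback preference (diagonal, then gap in the longer sequence's
partner, then the other gap) from the best-scoring endpoint; the argument
pair is canonicalized by (length, content) first, which makes the function
symmetric by construction. MAG→OTU linking takes the best identity, breaking
ties by longer alignment then lexicographic OTU id, and returns no link below
the cutoff (default 95%).

## Screening semantics

All thresholds are strict as phrased — length > 200 bp, identity > 95%,
relative abundance > 0.1% — except the hit count, where "fewer than 10
discarded" means keep iff ≥ 10. Reads are tried in both orientations and the
better identity used, since read orientation in public datasets is
arbitrary. The identity denominator of the original screening service is not
public; the overlap convention above is this package's documented stand-in.

## Numerical and design choices

- TSV dialect: UTF-8, tab-separated, `#` comments, `.` for missing numerics;
  readers reject structural defects (negative counts, non-integers,
  decreasing depths, missing mandatory columns) with coordinates rather than
  coercing, and every writer/reader pair round-trips exactly.
- GC content excludes ambiguity codes from the denominator (standard
  convention; excluded residues are logged). N50 is the largest L with
  sequences ≥ L covering half the total length.
- Depth convention: one sample = one depth midpoint in cm below seafloor,
  floats allowed.
- Reports print ratios to 1 decimal and fractions to 3, making identical
  config + seed reruns byte-identical.
- Pipeline seeding: the root seed spawns `simulate` and `bootstrap` child
  seeds; the config format rejects a separate synthetic seed so there is one
  seeding authority.

## Known limitations

- The generator's anoxic candidate floor and geochemistry companions are
  illustrative; conclusions about anoxic niches should not be read off them.
- Absolute abundances inherit every bias of the qPCR × relative-abundance
  recipe (extraction efficiency, copy number, primer bias); the package
  reproduces the convention, it does not correct it.
- The screening identity convention approximates, but cannot exactly match,
  services whose alignment parameters are unpublished.
- Ratio medians from counts are slightly biased upward at low NOB counts
  (Jensen effect of 1/N); at the default read depth the effect is well under
  the 10% verification tolerance.
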