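"""Guild attribution of OTUs and identity-based MAG-to-OTU linking.

Guild membership is decided by case-insensitive exact name matches at a
stated taxonomic rank (e.g. family ``Nitrospinaceae`` -> canonical NOB).
The candidate lineage is the exception: because its database classification
is unstable across reference releases, membership is driven solely by an
explicit, user-supplied list of verified OTU ids — an OTU whose taxonomy
merely looks like the candidate phylum but is not on the list stays
``other``.

Sequence identity uses a semi-global (overlap, free end-gap) alignment:
identity = matches / aligned columns, where terminal gap columns are
excluded so a short amplicon scored against a full-length 16S gene is
evaluated over the overlapping region only.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .tables import RANKS, Taxonomy

GUILD_AOA = "AOA"
GUILD_NITROSPIRACEAE = "NOB_Nitrospiraceae"
GUILD_NITROSPINACEAE = "NOB_Nitrospinaceae"
GUILD_CANDIDATE = "NOB_candidate"
GUILD_ANAMMOX = "anammox"
GUILD_OTHER = "other"

NOB_LINEAGES = (GUILD_NITROSPIRACEAE, GUILD_NITROSPINACEAE, GUILD_CANDIDATE)
CANONICAL_NOB = (GUILD_NITROSPIRACEAE, GUILD_NITROSPINACEAE)


@dataclasses.dataclass
class GuildConfig:
    """Guild -> list of (rank, name) patterns.

    ``candidate_phylum`` is informational: it marks putative candidate OTUs
    in the provenance notes but never grants membership by itself.
    """

    patterns: dict[str, list[tuple[str, str]]]
    candidate_phylum: str | None = "Schekmanbacteria"

    def __post_init__(self) -> None:
        for guild, pats in self.patterns.items():
            if not pats:
                raise ParameterError(f"guild {guild!r} has an empty pattern list")
            for rank, name in pats:
                if rank not in RANKS:
                    raise ParameterError(
                        f"guild {guild!r}: unknown rank {rank!r} (expected one of {RANKS})"
                    )
                if not name:
                    raise ParameterError(f"guild {guild!r}: empty pattern name at rank {rank!r}")

    @classmethod
    def default(cls) -> "GuildConfig":
        return cls(
            patterns={
                GUILD_AOA: [("family", "Nitrosopumilaceae")],
                GUILD_NITROSPIRACEAE: [("family", "Nitrospiraceae")],
                GUILD_NITROSPINACEAE: [("family", "Nitrospinaceae")],
                GUILD_ANAMMOX: [("order", "Brocadiales")],
            }
        )


@dataclasses.dataclass
class GuildMap:
    """Total map OTU id -> guild label, with a provenance note per assignment."""

    labels: dict[str, str]
    provenance: dict[str, str]

    def members(self, guild: str) -> list[str]:
        return [otu for otu, label in self.labels.items() if label == guild]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "otu_id": list(self.labels),
                "guild": [self.labels[o] for o in self.labels],
                "provenance": [self.provenance.get(o, "") for o in self.labels],
            }
        )


def assign_guilds(
    taxonomy: Taxonomy,
    config: GuildConfig | None = None,
    verified_candidate_otus: Sequence[str] = (),
) -> GuildMap:
    """Attribute every OTU in ``taxonomy`` to exactly one guild.

    A conflict — one OTU matching the patterns of two guilds, or a verified
    candidate OTU also matching another guild's pattern — is a hard error,
    never a silent priority. Verified candidate ids absent from the taxonomy
    are warned about and skipped. Output is independent of pattern order.
    """
    config = config or GuildConfig.default()
    verified = []
    for otu in verified_candidate_otus:
        if otu in taxonomy:
            verified.append(otu)
        else:
            warnings.warn(f"verified candidate OTU {otu!r} absent from taxonomy; skipped")
    verified_set = set(verified)

    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for otu, lineage in taxonomy.lineages.items():
        matches = []
        for guild in sorted(config.patterns):
            for rank, name in config.patterns[guild]:
                if lineage[RANKS.index(rank)].casefold() == name.casefold():
                    matches.append((guild, f"{rank}={name}"))
                    break
        if len(matches) > 1:
            raise ParameterError(
                f"OTU {otu!r} matches multiple guilds: "
                + ", ".join(f"{g} ({p})" for g, p in matches)
            )
        if otu in verified_set:
            if matches:
                raise ParameterError(
                    f"verified candidate OTU {otu!r} also matches guild "
                    f"{matches[0][0]} ({matches[0][1]})"
                )
            labels[otu] = GUILD_CANDIDATE
            provenance[otu] = "verified candidate list"
        elif matches:
            labels[otu], provenance[otu] = matches[0]
        else:
            labels[otu] = GUILD_OTHER
            note = "no guild pattern matched"
            if (
                config.candidate_phylum
                and lineage[RANKS.index("phylum")].casefold() == config.candidate_phylum.casefold()
            ):
                note = "putative candidate phylum but not in verified list"
            provenance[otu] = note
    return GuildMap(labels, provenance)


def write_guild_map(guild_map: GuildMap, path) -> None:
    guild_map.to_frame().to_csv(path, sep="\t", index=False)


def read_guild_map(path) -> GuildMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for colname in ("otu_id", "guild"):
        if colname not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {colname!r}")
    labels = dict(zip(df["otu_id"], df["guild"]))
    prov = dict(zip(df["otu_id"], df.get("provenance", pd.Series(dtype=str)).fillna("")))
    return GuildMap(labels, prov)


# ---------------------------------------------------------------------------
# pairwise identity (semi-global / overlap alignment)


@dataclasses.dataclass(frozen=True)
class AlignmentScoring:
    """Match +1, mismatch -1, linear gap -2, free terminal gaps."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


@dataclasses.dataclass(frozen=True)
class PairwiseIdentity:
    identity_percent: float
    alignment_length: int
    score: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().replace("U", "T").encode("ascii"), dtype=np.uint8)


def pairwise_identity(
    seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None
) -> PairwiseIdentity:
    """Percent identity of the best overlap alignment of two nucleotide sequences.

    The alignment maximizes the configured score with free end gaps in both
    sequences; identity = matches / aligned columns over the traced overlap
    (terminal gap columns excluded). The function is symmetric in its
    arguments: the pair is canonicalized by (length, content) before
    alignment. Ties between co-optimal alignments are resolved by a fixed
    traceback preference (diagonal, then gap in the second sequence, then gap
    in the first) from the endpoint with maximal score, preferring the
    endpoint that consumes more of both sequences.
    """
    sc = scoring or AlignmentScoring()
    if not seq_a or not seq_b:
        raise ParameterError("pairwise_identity requires two non-empty sequences")
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        seq_a, seq_b = seq_b, seq_a
    a = _encode(seq_a)
    b = _encode(seq_b)
    n, m = len(a), len(b)

    H = np.zeros((n + 1, m + 1))
    goff = sc.gap * np.arange(m + 1)
    V = np.empty(m + 1)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], sc.match, sc.mismatch)
        V[0] = 0.0
        np.maximum(H[i - 1, :m] + sub, H[i - 1, 1:] + sc.gap, out=V[1:])
        # H[i, j] = max_{k<=j} V[k] + gap*(j-k), via a prefix max
        H[i] = np.maximum.accumulate(V - goff) + goff

    # endpoint: best score on the last row or column; prefer larger i, then j
    best = max(H[n, :].max(), H[:, m].max())
    eps = 1e-6
    end = None
    for i in range(n, -1, -1):
        if abs(H[i, m] - best) < eps:
            end = (i, m)
            break
        if i == n:
            js = np.nonzero(np.abs(H[n, :] - best) < eps)[0]
            if len(js):
                end = (n, int(js[-1]))
                break
    assert end is not None
    i, j = end

    matches = 0
    cols = 0
    while i > 0 and j > 0:
        here = H[i, j]
        diag = H[i - 1, j - 1] + (sc.match if a[i - 1] == b[j - 1] else sc.mismatch)
        if abs(here - diag) < eps:
            matches += int(a[i - 1] == b[j - 1])
            i -= 1
            j -= 1
        elif abs(here - (H[i - 1, j] + sc.gap)) < eps:
            i -= 1
        else:
            j -= 1
        cols += 1

    identity = 100.0 * matches / cols if cols else 0.0
    return PairwiseIdentity(identity_percent=identity, alignment_length=cols, score=float(best))


@dataclasses.dataclass(frozen=True)
class MagOtuLink:
    """Best amplicon OTU match of a MAG 16S sequence, or none below the cutoff."""

    mag_id: str
    otu_id: str | None
    identity_percent: float
    alignment_length: int


def link_mag_to_otus(
    mag_16s: str,
    otus: Mapping[str, str],
    min_identity: float = 95.0,
    mag_id: str = "MAG",
    scoring: AlignmentScoring | None = None,
) -> MagOtuLink:
    """Link a MAG's 16S sequence to its best-identity OTU.

    Ties are broken by longer alignment, then lexicographically smaller OTU
    id. Returns a link with ``otu_id=None`` when the best identity falls
    below ``min_identity``.
    """
    if not otus:
        raise ParameterError("link_mag_to_otus requires at least one OTU sequence")
    best_key = None
    best: tuple[str, PairwiseIdentity] | None = None
    for otu_id in sorted(otus):
        result = pairwise_identity(mag_16s, otus[otu_id], scoring)
        key = (result.identity_percent, result.alignment_length)
        if best_key is None or key > best_key:
            best_key = key
            best = (otu_id, result)
    assert best is not None
    otu_id, result = best
    if result.identity_percent < min_identity:
        return MagOtuLink(mag_id, None, result.identity_percent, result.alignment_length)
    return MagOtuLink(mag_id, otu_id, result.identity_percent, result.alignment_length)
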