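"""Read-to-clonotype calling for targeted-gDNA TCR libraries.

The wet protocol ligates an adapter carrying a 4 bp validation barcode, a 6 bp
random UMI and a 4 bp library-ID barcode to each fragment end, and sequences
2x250 bp.  Processing is therefore:

1. quality/length filter (every base Phred > 20, mates >= 250 bp);
2. demultiplex by library ID and build a fragment-specific 12 bp UMI by
   concatenating the two 6 bp mate UMIs, then trim and collapse to a
   single-end representation;
3. scan each read against a library of 20-base identification tags placed
   15 bp from each segment's predicted RSS cleavage point (coding and signal
   flanks; shared "rtags" are resolved by secondary alt-tags at the nearest
   point of divergence);
4. for reads with a V and J tag in a recombination-compatible conformation,
   extract the CDR3 as the nucleotides between the predicted RSS cleavage
   points, or from the first position where homology to the germline
   reference diverges on the way to the cleavage point;
5. classify each V-CDR3-J cassette as productive (frame-preserving junction,
   no in-frame stop) or non-productive;
6. collapse PCR duplicates by degenerate 12 bp-UMI matching (up to two base
   mismatches) within each clonotype of a sample, and score clonotype
   expansion to build the per-sample repertoire.

Only productive coding-joint rearrangements enter the repertoire, and
delta-locus calls are excluded (alpha-locus recombination removes TRD, so
delta data are not comparable across samples).
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdapterLayout",
    "TagEntry",
    "TagLibrary",
    "TagHit",
    "JunctionCall",
    "Repertoire",
    "IncoherentJunctionError",
    "build_tag_library",
    "qc_filter",
    "demultiplex_and_parse_umi",
    "scan_tags",
    "find_conformation",
    "call_cdr3",
    "canonical_junction",
    "assess_productivity",
    "dedup_umis",
    "build_repertoire",
    "process_read_pairs",
    "read_fastq_pairs",
]

TAG_LEN = 20
TAG_OFFSET = 15  # bp between the tag and the predicted RSS cleavage point
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOPS = {"TAA", "TAG", "TGA"}
LOCUS_TO_CHAIN = {"TRA": "alpha", "TRB": "beta", "TRG": "gamma", "TRD": "delta"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class IncoherentJunctionError(ValueError):
    """V boundary lies beyond the J boundary: the call is rejected."""


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


# --------------------------------------------------------------------------
# Adapter layout and demultiplexing


@dataclass(frozen=True)
class AdapterLayout:
    """Fragment-end adapter structure: validation barcode + UMI + library ID."""

    validation_barcode: str
    library_id_map: Mapping[str, str]  # 4-mer -> sample id
    validation_barcode_len: int = 4
    umi_len: int = 6
    library_id_len: int = 4

    def __post_init__(self) -> None:
        if len(self.validation_barcode) != self.validation_barcode_len:
            raise ValueError("validation barcode length mismatch")
        ids = list(self.library_id_map)
        for lid in ids:
            if len(lid) != self.library_id_len:
                raise ValueError(f"library id {lid!r} is not {self.library_id_len} bp")
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if _hamming(a, b) < 2:
                    raise ValueError(f"library ids {a!r}/{b!r} are within Hamming distance 1")

    @property
    def prefix_len(self) -> int:
        return self.validation_barcode_len + self.umi_len + self.library_id_len


def qc_filter(read_pair, min_phred: int = 20, min_len: int = 250):
    """Pass iff every base of both mates has Phred > ``min_phred`` (strict)
    and each mate is at least ``min_len`` bp.  Returns ``(ok, reason)``."""
    for seq, qual in ((read_pair.seq1, read_pair.qual1), (read_pair.seq2, read_pair.qual2)):
        if len(seq) != len(qual):
            raise ValueError(f"malformed FASTQ record {read_pair.read_id!r}: "
                             "sequence/quality length mismatch")
        if len(seq) < min_len:
            return False, "length"
        if min(qual) <= min_phred:
            return False, "quality"
    return True, None


def demultiplex_and_parse_umi(read_pair, layout: AdapterLayout):
    """Validate both mate prefixes, extract and concatenate the mate UMIs
    (mate-1 UMI first), look up the library ID, and return the trimmed
    single-end representation.

    Returns ``(sample_id, umi12, trimmed_seq, reason)``; on failure the first
    three are None and ``reason`` names the bin ("invalid_barcode" or
    "unknown_library").
    """
    v, u, l = layout.validation_barcode_len, layout.umi_len, layout.library_id_len
    s1, s2 = read_pair.seq1, read_pair.seq2
    if s1[:v] != layout.validation_barcode or s2[:v] != layout.validation_barcode:
        return None, None, None, "invalid_barcode"
    umi12 = s1[v:v + u] + s2[v:v + u]
    lib = s1[v + u:v + u + l]
    sample = layout.library_id_map.get(lib)
    if sample is None:
        return None, None, None, "unknown_library"
    return sample, umi12, s1[layout.prefix_len:], None


# --------------------------------------------------------------------------
# Tag library


@dataclass(frozen=True)
class TagEntry:
    tag: str
    element: str
    segment_class: str  # V / D / J
    locus: str
    flank: str  # coding / signal
    offset_from_rss: int = TAG_OFFSET
    is_rtag: bool = False
    alt_tag: str | None = None
    alt_delta: int = 0  # read-coordinate offset of the alt-tag from the tag start
    allele_variants: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.tag) != TAG_LEN:
            raise ValueError("tags must be exactly 20 bases")


@dataclass
class TagLibrary:
    entries: list[TagEntry]

    def __post_init__(self) -> None:
        self._by_tag: dict[str, list[TagEntry]] = defaultdict(list)
        for e in self.entries:
            self._by_tag[e.tag].append(e)
            for var in e.allele_variants:
                self._by_tag[var].append(e)
        for tag, ents in self._by_tag.items():
            if len({(e.element, e.flank) for e in ents}) > 1 and not all(e.is_rtag for e in ents):
                raise ValueError(f"tag {tag!r} shared by several elements but not marked rtag")

    @property
    def tags(self) -> Mapping[str, list[TagEntry]]:
        return self._by_tag

    def to_tsv(self, path) -> None:
        rows = [{
            "tag": e.tag, "element": e.element, "class": e.segment_class,
            "locus": e.locus, "flank": e.flank, "offset": e.offset_from_rss,
            "rtag": int(e.is_rtag), "alt_tag": e.alt_tag or "",
            "alt_delta": e.alt_delta,
            "allele_variants": ",".join(e.allele_variants),
        } for e in self.entries]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TagLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        entries = [TagEntry(
            tag=r["tag"], element=r["element"], segment_class=r["class"],
            locus=r["locus"], flank=r["flank"], offset_from_rss=int(r["offset"]),
            is_rtag=bool(int(r["rtag"])), alt_tag=r["alt_tag"] or None,
            alt_delta=int(r["alt_delta"]),
            allele_variants=tuple(v for v in r["allele_variants"].split(",") if v),
        ) for r in df.to_dict("records")]
        return cls(entries)


def _tag_windows(segment) -> list[tuple[str, str, int]]:
    """(flank, tag, window_start) candidates for one germline segment."""
    seq, rss = segment.sequence, segment.rss_position
    out = []
    if segment.segment_class == "V":
        if rss >= TAG_OFFSET + TAG_LEN:
            out.append(("coding", seq[rss - TAG_OFFSET - TAG_LEN:rss - TAG_OFFSET],
                        rss - TAG_OFFSET - TAG_LEN))
        if len(seq) - rss >= TAG_OFFSET + TAG_LEN:
            out.append(("signal", seq[rss + TAG_OFFSET:rss + TAG_OFFSET + TAG_LEN],
                        rss + TAG_OFFSET))
    elif segment.segment_class == "J":
        if len(seq) - rss >= TAG_OFFSET + TAG_LEN:
            out.append(("coding", seq[rss + TAG_OFFSET:rss + TAG_OFFSET + TAG_LEN],
                        rss + TAG_OFFSET))
        if rss >= TAG_OFFSET + TAG_LEN:
            out.append(("signal", seq[rss - TAG_OFFSET - TAG_LEN:rss - TAG_OFFSET],
                        rss - TAG_OFFSET - TAG_LEN))
    elif segment.segment_class == "D":
        if len(seq) >= TAG_LEN:
            out.append(("coding", seq[:TAG_LEN], 0))
    return out


# direction (in read coordinates, forward conformation) in which an alt-tag
# window moves away from the RSS for each (class, flank)
_ALT_DIRECTION = {("V", "coding"): -1, ("V", "signal"): +1,
                  ("J", "coding"): +1, ("J", "signal"): -1,
                  ("D", "coding"): +1}


def build_tag_library(segments: Sequence, max_alt_shift: int = 40) -> TagLibrary:
    """Derive the 20-base tag library from a germline reference.

    One coding-flank and (where the segment is long enough) one signal-flank
    tag per segment, positioned 15 bp from the predicted RSS cleavage point.
    Identical tags shared by several elements become rtags; each then receives
    an alt-tag: the nearest 20-base window, moving away from the RSS, at which
    the sharing elements diverge.
    """
    raw: list[tuple] = []  # (segment, flank, tag, window_start)
    for seg in segments:
        for flank, tag, start in _tag_windows(seg):
            raw.append((seg, flank, tag, start))

    shared: dict[str, list[tuple]] = defaultdict(list)
    for item in raw:
        shared[item[2]].append(item)

    entries = []
    for tag, items in shared.items():
        distinct = {it[0].name for it in items}
        if len(distinct) == 1:
            seg, flank, _, _ = items[0]
            entries.append(TagEntry(tag=tag, element=seg.name,
                                    segment_class=seg.segment_class,
                                    locus=seg.locus, flank=flank))
            continue
        # rtag: find the nearest divergent window away from the RSS
        for seg, flank, _, start in items:
            direction = _ALT_DIRECTION[(seg.segment_class, flank)]
            alt, delta = None, 0
            for k in range(1, max_alt_shift + 1):
                s = start + direction * k
                if s < 0 or s + TAG_LEN > len(seg.sequence):
                    break
                window = seg.sequence[s:s + TAG_LEN]
                others = {o.sequence[o_start + direction * k:o_start + direction * k + TAG_LEN]
                          for o, _, _, o_start in items if o.name != seg.name
                          and 0 <= o_start + direction * k <= len(o.sequence) - TAG_LEN}
                if window not in others:
                    alt, delta = window, direction * k
                    break
            entries.append(TagEntry(tag=tag, element=seg.name,
                                    segment_class=seg.segment_class,
                                    locus=seg.locus, flank=flank,
                                    is_rtag=True, alt_tag=alt, alt_delta=delta))
    return TagLibrary(entries)


# --------------------------------------------------------------------------
# Tag scanning and junction calling


@dataclass(frozen=True)
class TagHit:
    entry: TagEntry
    position: int  # read coordinate of the tag start
    via_rtag: bool = False
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


def scan_tags(seq: str, tags: TagLibrary) -> list[TagHit]:
    """Exact-match scan of every tag (and allele variant) against one read.

    rtag occurrences are resolved through the alt-tag at its expected offset;
    if zero or several sharing elements match the alt window, the hit is
    reported as ambiguous.  An empty hit list is a valid outcome.
    """
    if len(seq) < TAG_LEN:
        return []
    hits: list[TagHit] = []
    for tag, ents in tags.tags.items():
        start = seq.find(tag)
        while start != -1:
            if len(ents) == 1 and not ents[0].is_rtag:
                hits.append(TagHit(ents[0], start))
            else:
                resolved = []
                for e in ents:
                    if e.alt_tag is None:
                        continue
                    s = start + e.alt_delta
                    if 0 <= s <= len(seq) - TAG_LEN and seq[s:s + TAG_LEN] == e.alt_tag:
                        resolved.append(e)
                if len(resolved) == 1:
                    hits.append(TagHit(resolved[0], start, via_rtag=True))
                else:
                    hits.append(TagHit(ents[0], start, via_rtag=True, ambiguous=True,
                                       candidates=tuple(e.element for e in ents)))
            start = seq.find(tag, start + 1)
    hits.sort(key=lambda h: h.position)
    return hits


def find_conformation(hits: Sequence[TagHit]):
    """Pick a V/J tag pair compatible with a recombination product.

    Coding joint: a V coding-flank tag upstream of a J coding-flank tag of the
    same locus.  Signal joint: a V signal-flank and J signal-flank tag of the
    same locus co-occurring on the read.  Returns
    ``(category, v_hit, j_hit)`` or ``None``.
    """
    usable = [h for h in hits if not h.ambiguous]
    v_cod = [h for h in usable if h.entry.segment_class == "V" and h.entry.flank == "coding"]
    j_cod = [h for h in usable if h.entry.segment_class == "J" and h.entry.flank == "coding"]
    for v in v_cod:
        for j in j_cod:
            if v.entry.locus == j.entry.locus and v.position < j.position:
                return "coding", v, j
    v_sig = [h for h in usable if h.entry.segment_class == "V" and h.entry.flank == "signal"]
    j_sig = [h for h in usable if h.entry.segment_class == "J" and h.entry.flank == "signal"]
    for v in v_sig:
        for j in j_sig:
            if v.entry.locus == j.entry.locus:
                return "signal", v, j
    return None


def _v_boundary(seq: str, vseg, v_tag_end: int) -> int:
    """Walk from the V tag end toward the predicted cleavage point.

    ``v_tag_end``: read position aligned to V index ``rss - TAG_OFFSET``.
    Returns the read position of the junction start (first divergence from
    germline, else the predicted cleavage point).
    """
    rss = vseg.rss_position
    for k in range(TAG_OFFSET):
        x = v_tag_end + k
        if x >= len(seq) or seq[x] != vseg.sequence[rss - TAG_OFFSET + k]:
            return x
    return v_tag_end + TAG_OFFSET


def _j_boundary(seq: str, jseg, j_tag_start: int) -> int:
    """Walk from the J tag start back toward the predicted cleavage point.

    ``j_tag_start``: read position aligned to J index ``rss + TAG_OFFSET``.
    Returns the read position one past the junction end.
    """
    rss = jseg.rss_position
    for k in range(1, TAG_OFFSET + 1):
        x = j_tag_start - k
        if x < 0 or seq[x] != jseg.sequence[rss + TAG_OFFSET - k]:
            return x + 1
    return j_tag_start - TAG_OFFSET


@dataclass(frozen=True)
class JunctionCall:
    sample_id: str
    v_name: str
    j_name: str
    cdr3_nt: str
    locus: str
    category: str  # coding / signal
    productive: bool
    umi12: str
    read_id: str
    d_name: str | None = None
    nonproductive_reason: str | None = None
    v_end: int | None = None  # V-coordinate junction start
    j_start: int | None = None  # J-coordinate junction end

    @property
    def chain(self) -> str:
        return LOCUS_TO_CHAIN[self.locus]

    @property
    def clonotype(self) -> tuple[str, str, str]:
        return (self.v_name, self.cdr3_nt, self.j_name)


def call_cdr3(seq: str, v_hit: TagHit, j_hit: TagHit, tags: TagLibrary,
              segments_by_name: Mapping[str, object],
              sample_id: str = "", umi12: str = "", read_id: str = "",
              d_hit: TagHit | None = None) -> JunctionCall:
    """Extract the CDR3 between the V and J boundaries of a coding joint.

    Boundaries are the predicted RSS cleavage points, pulled in to the first
    position at which the read diverges from the germline reference while
    walking from each tag toward its cleavage point.  Raises
    :class:`IncoherentJunctionError` when the boundaries cross.
    """
    vseg = segments_by_name[v_hit.entry.element]
    jseg = segments_by_name[j_hit.entry.element]
    vb = _v_boundary(seq, vseg, v_hit.position + TAG_LEN)
    jb = _j_boundary(seq, jseg, j_hit.position)
    if vb > jb:
        raise IncoherentJunctionError(
            f"V boundary {vb} beyond J boundary {jb} on read {read_id!r}")
    cdr3 = seq[vb:jb]
    # junction coordinates in segment space (for frame assessment)
    v_end = vseg.rss_position - (v_hit.position + TAG_LEN + TAG_OFFSET - vb)
    j_start = jseg.rss_position + (jb - (j_hit.position - TAG_OFFSET))
    d_name = None
    if d_hit is not None:
        d_name = d_hit.entry.element
    else:
        for tag, ents in tags.tags.items():
            if ents[0].segment_class == "D" and ents[0].locus == vseg.locus and tag in cdr3:
                d_name = ents[0].element
                break
    productive, reason = assess_productivity(vseg, cdr3, jseg, v_end=v_end, j_start=j_start)
    return JunctionCall(
        sample_id=sample_id, v_name=vseg.name, j_name=jseg.name, cdr3_nt=cdr3,
        locus=vseg.locus, category="coding", productive=productive,
        nonproductive_reason=reason, umi12=umi12, read_id=read_id,
        d_name=d_name, v_end=v_end, j_start=j_start)


def canonical_junction(seq: str, vseg, jseg):
    """Boundary walk applied to a full error-free cassette (V at position 0,
    J tail flush with the end).  Returns ``(v_end, j_start, cdr3)`` with
    ``v_end``/``j_start`` in V/J segment coordinates -- the same convention as
    :func:`call_cdr3`, so simulated truth and calls are directly comparable.

    Raises :class:`IncoherentJunctionError` when chance matches make the
    boundaries cross.
    """
    rss_v, rss_j = vseg.rss_position, jseg.rss_position
    vb = rss_v
    for i in range(rss_v - TAG_OFFSET, rss_v):
        if i >= len(seq) or seq[i] != vseg.sequence[i]:
            vb = i
            break
    off = len(seq) - len(jseg.sequence)
    jb = rss_j + off
    for k in range(1, TAG_OFFSET + 1):
        x = rss_j + TAG_OFFSET + off - k
        if x >= len(seq) or x < 0 or seq[x] != jseg.sequence[x - off]:
            jb = x + 1
            break
    if vb > jb:
        raise IncoherentJunctionError("boundaries cross in simulated cassette")
    return vb, jb - off, seq[vb:jb]


def assess_productivity(vseg, cdr3_nt: str, jseg,
                        v_end: int | None = None, j_start: int | None = None):
    """Frame and stop-codon assessment of a V-CDR3-J cassette.

    The cassette is productive iff the V reading frame is carried through the
    junction into the J frame and no in-frame stop codon occurs anywhere in
    the assembled cassette.  ``v_end``/``j_start`` give the junction
    boundaries in segment coordinates (default: the RSS cleavage points).
    Returns ``(productive, reason)`` with reason in
    {None, "out-of-frame", "stop"}.
    """
    if getattr(vseg, "coding_frame", None) is None or getattr(jseg, "coding_frame", None) is None:
        raise ValueError("segments must carry coding_frame annotations")
    if v_end is None:
        v_end = vseg.rss_position
    if j_start is None:
        j_start = jseg.rss_position
    # J codon starts sit at J indices == rss + coding_frame (mod 3); V is
    # translated in frame 0 from its 5' end
    in_frame = (v_end + len(cdr3_nt) + jseg.rss_position + jseg.coding_frame - j_start) % 3 == 0
    if not in_frame:
        return False, "out-of-frame"
    cassette = vseg.sequence[:v_end] + cdr3_nt + jseg.sequence[j_start:]
    for i in range(0, len(cassette) - 2, 3):
        if cassette[i:i + 3] in _STOPS:
            return False, "stop"
    return True, None


# --------------------------------------------------------------------------
# UMI deduplication and repertoire construction


def dedup_umis(umis: Sequence[str], max_mismatch: int = 2, umi_len: int = 12):
    """Collapse degenerate UMIs: molecules whose 12 bp fragment UMIs are
    within ``max_mismatch`` substitutions (transitively) count as one.

    Returns ``(n_molecules, clusters)`` where clusters maps each distinct UMI
    to its cluster index.  Single-linkage connected components over the
    <=2-mismatch graph; duplicate UMI strings trivially share a cluster.
    """
    uniq = list(dict.fromkeys(umis))
    for u in uniq:
        if len(u) != umi_len:
            raise ValueError(f"UMI {u!r} is not {umi_len} bp")
    n = len(uniq)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _hamming(uniq[i], uniq[j]) <= max_mismatch:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = {}
    clusters = {}
    for i, u in enumerate(uniq):
        r = find(i)
        clusters[u] = roots.setdefault(r, len(roots))
    return len(roots), clusters


@dataclass
class Repertoire:
    """Per-sample clonotype table: (V, CDR3, J) -> deduplicated molecule count.

    Only productive coding-joint rearrangements are included and delta-locus
    rows are excluded.  The D segment, where identified, is annotation
    (``d_names``), not part of the clonotype key: the toy CDR3 nucleotides
    already contain the D-derived bases.
    """

    sample_id: str
    counts: dict = field(default_factory=dict)  # (v, cdr3, j) -> count
    cell_type: str = ""
    chain: str = ""
    d_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            if c < 1:
                raise ValueError(f"clonotype {key} has count {c} < 1")

    @property
    def richness(self) -> int:
        return len(self.counts)

    @property
    def total_molecules(self) -> int:
        return sum(self.counts.values())

    def to_clonotype_vector(self):
        from .diversity import ClonotypeVector

        return ClonotypeVector(self.sample_id, np.fromiter(self.counts.values(), dtype=np.int64,
                                                           count=len(self.counts)))

    def to_airr(self, path) -> None:
        rows = [{
            "sequence_id": f"{self.sample_id}.{i}",
            "v_call": v, "d_call": self.d_names.get((v, cdr3, j), ""), "j_call": j,
            "junction": cdr3, "productive": "T", "duplicate_count": c,
        } for i, ((v, cdr3, j), c) in enumerate(sorted(self.counts.items()))]
        pd.DataFrame(rows, columns=["sequence_id", "v_call", "d_call", "j_call",
                                    "junction", "productive", "duplicate_count"]
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_airr(cls, path, sample_id: str = "", cell_type: str = "", chain: str = "") -> "Repertoire":
        df = pd.read_csv(path, sep="\t", dtype={"junction": str}, keep_default_na=False)
        counts, d_names = {}, {}
        for r in df.to_dict("records"):
            key = (r["v_call"], r["junction"], r["j_call"])
            counts[key] = counts.get(key, 0) + int(r["duplicate_count"])
            if r.get("d_call"):
                d_names[key] = r["d_call"]
        return cls(sample_id=sample_id, counts=counts, cell_type=cell_type,
                   chain=chain, d_names=d_names)


def build_repertoire(calls: Sequence[JunctionCall], sample_id: str | None = None,
                     cell_type: str = "", chain: str = "") -> Repertoire:
    """Aggregate junction calls of one sample into a deduplicated repertoire.

    Keeps productive coding joints, excludes delta-locus calls (logged via the
    returned repertoire's ``excluded_trd`` attribute would be overkill; the
    count is returned in ``repertoire.metadata``-free fashion by the caller
    report), groups by clonotype and collapses PCR duplicates by degenerate
    UMI matching.
    """
    samples = {c.sample_id for c in calls}
    if sample_id is None:
        if len(samples) > 1:
            raise ValueError(f"calls span several samples: {sorted(samples)}")
        sample_id = next(iter(samples)) if samples else ""
    elif samples - {sample_id}:
        raise ValueError(f"calls span several samples: {sorted(samples)}")

    by_clone: dict[tuple, list[str]] = defaultdict(list)
    d_names: dict[tuple, str] = {}
    for c in calls:
        if c.category != "coding" or not c.productive or c.locus == "TRD":
            continue
        by_clone[c.clonotype].append(c.umi12)
        if c.d_name:
            d_names.setdefault(c.clonotype, c.d_name)
    counts = {}
    for key, umis in by_clone.items():
        n, _ = dedup_umis(umis)
        counts[key] = n
    return Repertoire(sample_id=sample_id, counts=counts, cell_type=cell_type,
                      chain=chain, d_names=d_names)


# --------------------------------------------------------------------------
# End-to-end read processing


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    seq1: str
    qual1: Sequence[int]
    seq2: str
    qual2: Sequence[int]


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (Sanger Phred+33)."""
    from Bio import SeqIO

    for r1, r2 in zip(SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")):
        yield ReadPair(
            read_id=r1.id.rsplit("/", 1)[0],
            seq1=str(r1.seq), qual1=r1.letter_annotations["phred_quality"],
            seq2=str(r2.seq), qual2=r2.letter_annotations["phred_quality"],
        )


def process_read_pairs(pairs: Iterable[ReadPair], layout: AdapterLayout,
                       tags: TagLibrary, segments: Sequence,
                       min_phred: int = 20, min_len: int = 250):
    """Run QC -> demux/UMI -> tag scan -> junction call over read pairs.

    Returns ``(calls, report)``.  Every input pair lands in exactly one report
    bin, so the bin totals sum to the input count (conservation).  Reads are
    scanned on both strands; the orientation yielding a compatible V->J
    conformation is used.
    """
    calls: list[JunctionCall] = []
    bins: Counter = Counter()
    n = 0
    for pair in pairs:
        n += 1
        ok, reason = qc_filter(pair, min_phred=min_phred, min_len=min_len)
        if not ok:
            bins[f"qc_fail_{reason}"] += 1
            continue
        sample, umi12, trimmed, reason = demultiplex_and_parse_umi(pair, layout)
        if sample is None:
            bins[reason] += 1
            continue
        conf = None
        for seq in (trimmed, revcomp(trimmed)):
            conf = find_conformation(scan_tags(seq, tags))
            if conf is not None:
                break
        if conf is None:
            bins["no_conformation"] += 1
            continue
        category, v_hit, j_hit = conf
        if category == "signal":
            vseg = {s.name: s for s in segments}[v_hit.entry.element]
            calls.append(JunctionCall(
                sample_id=sample, v_name=v_hit.entry.element,
                j_name=j_hit.entry.element, cdr3_nt="", locus=vseg.locus,
                category="signal", productive=False,
                nonproductive_reason="signal-joint", umi12=umi12,
                read_id=pair.read_id))
            bins["called_signal"] += 1
            continue
        try:
            call = call_cdr3(seq, v_hit, j_hit, tags,
                             {s.name: s for s in segments},
                             sample_id=sample, umi12=umi12, read_id=pair.read_id)
        except IncoherentJunctionError:
            bins["incoherent_junction"] += 1
            continue
        calls.append(call)
        bins["called_coding"] += 1
    report = {"n_input": n, "bins": dict(bins)}
    report["conserved"] = sum(bins.values()) == n
    return calls, report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
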