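"""Synthetic germlines, repertoires, cohorts and UMI-tagged paired reads.

The simulator provides every input the analysis consumes, with the
statistical structure the method assumes:

* toy germline references per locus (TRA/TRB/TRG; D segments only at TRB)
  whose segments are pairwise distinguishable by 20-mers, so a tag library
  can be derived from them;
* V(D)J recombination events with exonucleolytic trimming and random
  N-nucleotide insertion, with truth junctions canonicalised by the same
  divergence-walk rule the caller uses;
* per-sample repertoires: mostly singleton clonotypes plus a configurable
  fraction of expanded clones, with rearrangement depths spanning orders of
  magnitude across a cohort;
* cohorts of labelled groups in which a between-group shift in the expanded
  fraction (``effect_delta``) creates a detectable diversity difference
  (``effect_delta = 0`` gives exchangeable groups for null calibration);
* 2x250 bp read pairs carrying the adapter layout (4 bp validation barcode,
  6 bp mate UMI, 4 bp library ID), PCR duplication with degenerate UMI
  copies, and uniform substitution errors -- plus truth tables, so the whole
  read-to-clonotype chain is testable without external data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clonocall import (AdapterLayout, IncoherentJunctionError, Repertoire,
                        assess_productivity, canonical_junction, revcomp)

__all__ = [
    "GermlineSegment",
    "RepertoireSpec",
    "GroupSpec",
    "CohortSpec",
    "ReadSimSpec",
    "RecombinationEvent",
    "SimulatedSample",
    "InvalidReferenceError",
    "make_germline_reference",
    "simulate_recombination",
    "simulate_repertoire",
    "simulate_cohort",
    "simulate_reads",
    "write_paired_fastq",
    "default_layout",
    "CHAIN_TO_LOCUS",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
CHAIN_TO_LOCUS = {"alpha": "TRA", "beta": "TRB", "gamma": "TRG"}

# toy segment geometry: enough flank on each side of the RSS for a 20-base
# tag 15 bp away, plus room for alt-tags
V_CODING_LEN = 90   # multiple of 3: V translated in frame 0 from its start
V_SIGNAL_LEN = 40
J_SIGNAL_LEN = 40
J_CODING_LEN = 70
D_LEN = 30


class InvalidReferenceError(ValueError):
    pass


@dataclass(frozen=True)
class GermlineSegment:
    name: str
    locus: str  # TRA / TRB / TRG
    segment_class: str  # V / D / J
    sequence: str
    rss_position: int  # 0-based offset of the predicted RSS cleavage point
    coding_frame: int | None = None  # frame phase at the RSS-proximal end (V/J)

    def __post_init__(self) -> None:
        if not (0 <= self.rss_position <= len(self.sequence)):
            raise ValueError("rss_position outside sequence")
        if set(self.sequence) - set(_BASES):
            raise ValueError("sequence alphabet must be A/C/G/T")
        if self.locus in ("TRA", "TRG") and self.segment_class == "D":
            raise ValueError(f"{self.locus} carries no D segments")


def _random_codons(rng, n_codons: int) -> str:
    codons = [a + b + c for a, b, c in itertools.product(_BASES, repeat=3)]
    codons = [c for c in codons if c not in _STOPS]
    return "".join(rng.choice(codons, size=n_codons))


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _kmers(seq: str, k: int = 20):
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def make_germline_reference(n_v: int, n_d: int, n_j: int, locus: str = "TRB",
                            seed: int = 0) -> list[GermlineSegment]:
    """Generate a toy germline reference for one locus.

    V segments: 90 bp stop-free coding region (translated in frame 0 from the
    5' end) followed by a 40 bp signal flank; the RSS cleavage point sits at
    the boundary.  J segments: 40 bp signal flank, then a coding region whose
    designated reading frame starts ``coding_frame`` bases past the cleavage
    point and is stop-free to the segment end.  D segments (TRB only): 30 bp,
    fully junction-proximal.  All segments are pairwise distinguishable by
    every one of their 20-mers (regenerated on collision), so unique tags can
    be derived.
    """
    if locus not in ("TRA", "TRB", "TRG"):
        raise InvalidReferenceError(f"unsupported locus {locus!r}")
    if n_v < 1 or n_j < 1:
        raise InvalidReferenceError("need at least one V and one J segment")
    if n_d and locus != "TRB":
        raise InvalidReferenceError(f"{locus} carries no D segments")
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    seen: set[str] = set()

    def add(name, cls, builder):
        for _ in range(100):
            seg = builder()
            km = _kmers(seg.sequence)
            if km & seen:
                continue
            seen.update(km)
            segments.append(seg)
            return
        raise InvalidReferenceError("could not generate distinguishable segments")

    for i in range(n_v):
        name = f"{locus}V{i + 1}"
        add(name, "V", lambda name=name: GermlineSegment(
            name=name, locus=locus, segment_class="V",
            sequence=_random_codons(rng, V_CODING_LEN // 3) + _random_seq(rng, V_SIGNAL_LEN),
            rss_position=V_CODING_LEN, coding_frame=V_CODING_LEN % 3))
    for i in range(n_d):
        name = f"{locus}D{i + 1}"
        add(name, "D", lambda name=name: GermlineSegment(
            name=name, locus=locus, segment_class="D",
            sequence=_random_seq(rng, D_LEN), rss_position=0, coding_frame=None))
    for i in range(n_j):
        name = f"{locus}J{i + 1}"

        def build_j(name=name):
            frame = int(rng.integers(0, 3))
            head = _random_seq(rng, J_SIGNAL_LEN + frame)
            n_codons = (J_CODING_LEN - frame) // 3
            tail_pad = (J_CODING_LEN - frame) % 3
            seq = head + _random_codons(rng, n_codons) + _random_seq(rng, tail_pad)
            return GermlineSegment(name=name, locus=locus, segment_class="J",
                                   sequence=seq, rss_position=J_SIGNAL_LEN,
                                   coding_frame=frame)

        add(name, "J", build_j)
    return segments


@dataclass(frozen=True)
class RecombinationEvent:
    v_name: str
    j_name: str
    cdr3_nt: str
    sequence: str  # full V(+junction)+J coding cassette, V starts at 0
    productive: bool
    locus: str
    chain: str
    d_name: str | None = None
    v_end: int = 0
    j_start: int = 0

    @property
    def clonotype(self) -> tuple[str, str, str]:
        return (self.v_name, self.cdr3_nt, self.j_name)


def _trim(rng, p: float = 0.35, cap: int = 12) -> int:
    return min(int(rng.geometric(p)) - 1, cap)


def simulate_recombination(segments: Sequence[GermlineSegment], chain: str,
                           rng, insert_mean: float = 4.0) -> RecombinationEvent:
    """Draw one V(D)J coding-joint recombination.

    Exonuclease trimming (geometric, capped below the tag offset so the tags
    survive) removes bases from the RSS-proximal ends; random N nucleotides
    are inserted; TRB joints additionally include a trimmed D core.  The
    truth CDR3 is canonicalised with the caller's divergence-walk rule, and
    productivity is assessed with the caller's own frame/stop implementation.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    locus = CHAIN_TO_LOCUS.get(chain)
    if locus is None:
        raise InvalidReferenceError(f"unknown chain {chain!r}")
    vs = [s for s in segments if s.locus == locus and s.segment_class == "V"]
    js = [s for s in segments if s.locus == locus and s.segment_class == "J"]
    ds = [s for s in segments if s.locus == locus and s.segment_class == "D"]
    if not vs or not js:
        raise InvalidReferenceError(f"no V/J segments for locus {locus}")
    if locus == "TRB" and not ds:
        raise InvalidReferenceError("TRB requires D segments")

    while True:
        v = vs[rng.integers(len(vs))]
        j = js[rng.integers(len(js))]
        tv, tj = _trim(rng), _trim(rng)
        n1 = _random_seq(rng, min(int(rng.poisson(insert_mean)), 12))
        middle = n1
        d_name = None
        if locus == "TRB":
            d = ds[rng.integers(len(ds))]
            d5, d3 = _trim(rng, 0.5, 10), _trim(rng, 0.5, 10)
            core = d.sequence[d5:len(d.sequence) - d3]
            if len(core) < 3:
                core = d.sequence[:3]
            n2 = _random_seq(rng, min(int(rng.poisson(insert_mean)), 12))
            middle = n1 + core + n2
            d_name = d.name
        seq = v.sequence[:v.rss_position - tv] + middle + j.sequence[j.rss_position + tj:]
        try:
            v_end, j_start, cdr3 = canonical_junction(seq, v, j)
        except IncoherentJunctionError:
            continue  # pathological chance matches; redraw
        productive, _ = assess_productivity(v, cdr3, j, v_end=v_end, j_start=j_start)
        return RecombinationEvent(
            v_name=v.name, j_name=j.name, cdr3_nt=cdr3, sequence=seq,
            productive=productive, locus=locus, chain=chain, d_name=d_name,
            v_end=v_end, j_start=j_start)


# --------------------------------------------------------------------------
# Repertoires


@dataclass(frozen=True)
class RepertoireSpec:
    """Target structure of one sample's clonotype count vector."""

    n_clonotypes: int
    total_rearrangements: int | None = None
    expansion_fraction: float = 0.1
    expansion_shape: float = 0.25  # success prob of the geometric excess law
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be positive")
        if not (0.0 <= self.expansion_fraction <= 1.0):
            raise ValueError("expansion_fraction must lie in [0, 1]")
        if not (0.0 < self.expansion_shape <= 1.0):
            raise ValueError("expansion_shape must lie in (0, 1]")
        if (self.total_rearrangements is not None
                and self.total_rearrangements < self.n_clonotypes):
            raise ValueError("total_rearrangements must be >= n_clonotypes")


def _composition(rng, total: int, parts: int) -> np.ndarray:
    """Uniformly random composition of ``total`` into ``parts`` positive ints.

    This is the exact conditional law of i.i.d. geometric sizes given their
    sum (the geometric pmf depends on the values only through the sum), so it
    is the natural way to draw heavy-tailed clone sizes under an exact total.
    """
    if parts == 1:
        return np.array([total])
    cuts = np.sort(rng.choice(total - 1, size=parts - 1, replace=False)) + 1
    return np.diff(np.concatenate(([0], cuts, [total])))


def simulate_clone_sizes(spec: RepertoireSpec, rng=None) -> np.ndarray:
    """Clone-size vector: singletons plus a fraction of expanded clones.

    With ``total_rearrangements`` set, the excess over one read per clonotype
    is spread over the expanded clones as a uniformly random composition
    (conditional-geometric law), so the counts sum to the total exactly.
    With ``total_rearrangements=None``, expanded clones draw sizes
    ``1 + Geometric(expansion_shape)`` i.i.d.
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_clonotypes
    sizes = np.ones(n, dtype=np.int64)
    m = int(round(spec.expansion_fraction * n))
    if spec.total_rearrangements is None:
        if m > 0:
            sizes[:m] += rng.geometric(spec.expansion_shape, size=m)
    else:
        excess = spec.total_rearrangements - n
        if excess > 0:
            if m == 0:
                # no expanded clones: spread the excess as evenly as possible
                sizes += excess // n
                sizes[:excess % n] += 1
            else:
                m = min(m, excess)
                sizes[:m] += _composition(rng, excess, m)
    rng.shuffle(sizes)
    return sizes


def simulate_repertoire(spec: RepertoireSpec, segments: Sequence[GermlineSegment],
                        chain: str = "beta", sample_id: str = "sim",
                        rng=None) -> tuple[Repertoire, pd.DataFrame]:
    """Draw a repertoire of distinct productive clonotypes with clone sizes
    from :func:`simulate_clone_sizes`.  Returns the repertoire and a truth
    table (one row per clonotype: segment names, junction, full cassette,
    count)."""
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    sizes = simulate_clone_sizes(spec, rng)
    events: dict[tuple, RecombinationEvent] = {}
    guard = 0
    while len(events) < spec.n_clonotypes:
        ev = simulate_recombination(segments, chain, rng)
        guard += 1
        if guard > 50 * spec.n_clonotypes + 1000:
            raise RuntimeError("could not draw enough distinct productive clonotypes")
        if ev.productive and ev.clonotype not in events:
            events[ev.clonotype] = ev
    evs = list(events.values())
    counts = {ev.clonotype: int(c) for ev, c in zip(evs, sizes)}
    rep = Repertoire(sample_id=sample_id, counts=counts, chain=chain,
                     d_names={ev.clonotype: ev.d_name for ev in evs if ev.d_name})
    truth = pd.DataFrame({
        "sample_id": sample_id,
        "v_call": [e.v_name for e in evs],
        "d_call": [e.d_name or "" for e in evs],
        "j_call": [e.j_name for e in evs],
        "junction": [e.cdr3_nt for e in evs],
        "sequence": [e.sequence for e in evs],
        "count": [counts[e.clonotype] for e in evs],
    })
    return rep, truth


# --------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n_samples: int
    expansion_fraction: float = 0.1
    expansion_shape: float = 0.25

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: labelled groups plus an optional expansion effect.

    ``effect_delta`` is added to ``expansion_fraction`` for the groups named
    in ``affected_groups``; with ``effect_delta = 0`` the groups are
    exchangeable.  Per-sample depths are drawn log-uniformly from
    ``depth_range`` and the clonotype richness is ``richness_fraction`` of
    the depth.
    """

    groups: tuple[GroupSpec, ...]
    effect_delta: float = 0.0
    affected_groups: tuple[str, ...] = ()
    depth_range: tuple[float, float] = (1e3, 1e5)
    richness_fraction: float = 0.5
    cell_type: str = "CD8"
    chain: str = "beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if not (0 < self.depth_range[0] <= self.depth_range[1]):
            raise ValueError("invalid depth range")
        for g in self.groups:
            f = g.expansion_fraction + (self.effect_delta if g.label in self.affected_groups else 0)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"effective expansion_fraction {f} outside [0, 1] "
                                 f"for group {g.label}")


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    repertoire: Repertoire
    truth: pd.DataFrame | None = None


def simulate_cohort(cspec: CohortSpec, segments: Sequence[GermlineSegment] | None = None,
                    sequence_level: bool = False) -> list[SimulatedSample]:
    """Simulate a labelled cohort of repertoires.

    By default clonotypes are abstract identifiers (only the count structure
    matters downstream of the caller); with ``sequence_level=True`` full
    recombination events are drawn instead, which requires ``segments`` and
    is meant for small read-level round-trip studies.
    """
    rng = np.random.default_rng(cspec.seed)
    if sequence_level and segments is None:
        raise ValueError("sequence_level cohorts need a germline reference")
    out: list[SimulatedSample] = []
    k = 0
    for g in cspec.groups:
        frac = g.expansion_fraction + (cspec.effect_delta if g.label in cspec.affected_groups else 0.0)
        for _ in range(g.n_samples):
            k += 1
            sample_id = f"S{k:03d}"
            lo, hi = np.log(cspec.depth_range[0]), np.log(cspec.depth_range[1])
            depth = int(round(np.exp(rng.uniform(lo, hi))))
            n_clono = max(2, int(round(cspec.richness_fraction * depth)))
            spec = RepertoireSpec(n_clonotypes=n_clono, total_rearrangements=depth,
                                  expansion_fraction=frac)
            if sequence_level:
                rep, truth = simulate_repertoire(spec, segments, chain=cspec.chain,
                                                 sample_id=sample_id, rng=rng)
            else:
                sizes = simulate_clone_sizes(spec, rng)
                counts = {(f"{sample_id}.c{i}", "", ""): int(c) for i, c in enumerate(sizes)}
                rep = Repertoire(sample_id=sample_id, counts=counts,
                                 cell_type=cspec.cell_type, chain=cspec.chain)
                truth = None
            rep.cell_type = cspec.cell_type
            out.append(SimulatedSample(sample_id=sample_id, group=g.label,
                                       repertoire=rep, truth=truth))
    return out


def cohort_metadata(samples: Sequence[SimulatedSample]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "group": [s.group for s in samples],
        "cell_type": [s.repertoire.cell_type for s in samples],
        "chain": [s.repertoire.chain for s in samples],
    })


def two_group_cohort(n_per_group: int = 20, effect_delta: float = 0.3,
                     base_fraction: float = 0.05,
                     depth_range: tuple[float, float] = (1e3, 1e4),
                     seed: int = 0, chain: str = "beta") -> CohortSpec:
    """Convenience two-group design (group B carries the expansion effect)."""
    return CohortSpec(
        groups=(GroupSpec("A", n_per_group, expansion_fraction=base_fraction),
                GroupSpec("B", n_per_group, expansion_fraction=base_fraction)),
        effect_delta=effect_delta, affected_groups=("B",),
        depth_range=depth_range, chain=chain, seed=seed)


# --------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadSimSpec:
    pcr_duplication_mean: float = 1.0
    error_rate: float = 0.0
    umi_error_max: int = 2
    fragment_length_range: tuple[int, int] = (250, 350)
    read_len: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.umi_error_max > 2:
            raise ValueError("umi_error_max > 2 defeats the dedup rule")
        if self.pcr_duplication_mean < 0:
            raise ValueError("pcr_duplication_mean must be >= 0")


def default_layout(sample_ids: Sequence[str]) -> AdapterLayout:
    """Adapter layout with one library ID per sample (Hamming distance >= 2)."""
    pool = ["AACC", "GGTT", "ACGT", "CATG", "TGCA", "GTAC", "CCGG", "TTAA",
            "AGCT", "GACT", "CTGA", "TCAG"]
    if len(sample_ids) > len(pool):
        raise ValueError("too many samples for the built-in library-ID pool")
    return AdapterLayout(validation_barcode="ACTG",
                         library_id_map=dict(zip(pool, sample_ids)))


def _mutate(rng, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


def _seq_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    flips = rng.random(len(seq)) < rate
    if not flips.any():
        return seq
    out = list(seq)
    for p in np.flatnonzero(flips):
        out[p] = rng.choice([b for b in _BASES if b != out[p]])
    return "".join(out)


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq1: str
    seq2: str


def simulate_reads(truth: pd.DataFrame, rspec: ReadSimSpec, layout: AdapterLayout,
                   rng=None) -> tuple[list[SimulatedRead], pd.DataFrame]:
    """Turn a repertoire truth table into UMI-tagged 2x250 bp read pairs.

    Each of a clonotype's ``count`` molecules receives a distinct 12 bp
    fragment UMI (6 bp per mate); PCR copies reuse the molecule's UMI with at
    most ``umi_error_max`` substitutions; substitution errors are injected at
    ``error_rate`` across the whole read.  Returns the reads and a read-truth
    table (read id -> molecule id -> clonotype).
    """
    rng = np.random.default_rng(rspec.seed if rng is None else rng)
    # independent stream for base errors, so read structure (fragments, UMIs,
    # PCR copies) is identical across error rates under one seed
    err_rng = np.random.default_rng(int(rng.integers(2**31)))
    v = layout.validation_barcode
    lib_of_sample = {s: lid for lid, s in layout.library_id_map.items()}
    if layout.prefix_len >= rspec.read_len:
        raise ValueError("adapter layout longer than the read")
    payload = rspec.read_len - layout.prefix_len
    reads: list[SimulatedRead] = []
    truth_rows = []
    mol_id = 0
    for row in truth.to_dict("records"):
        sample = row["sample_id"]
        lib = lib_of_sample[sample]
        cassette = row["sequence"]
        for _ in range(int(row["count"])):
            mol_id += 1
            u = int(rng.integers(0, 51))  # fragment start inside the V segment
            lo, hi = rspec.fragment_length_range
            frag_len = int(rng.integers(lo, hi + 1))
            frag = cassette[u:]
            if len(frag) < frag_len:
                frag = frag + _random_seq(rng, frag_len - len(frag))
            else:
                frag = frag[:frag_len]
            umi1, umi2 = _random_seq(rng, 6), _random_seq(rng, 6)
            n_copies = 1 + int(rng.poisson(rspec.pcr_duplication_mean))
            for copy in range(n_copies):
                umi12 = umi1 + umi2
                if copy > 0 and rspec.umi_error_max > 0:
                    umi12 = _mutate(rng, umi12, int(rng.integers(0, rspec.umi_error_max + 1)))
                cu1, cu2 = umi12[:6], umi12[6:]
                s1 = v + cu1 + lib + frag[:payload]
                s2 = v + cu2 + lib + revcomp(frag)[:payload]
                s1 = _seq_errors(err_rng, s1, rspec.error_rate)
                s2 = _seq_errors(err_rng, s2, rspec.error_rate)
                rid = f"{sample}.m{mol_id}.c{copy}"
                reads.append(SimulatedRead(read_id=rid, seq1=s1, seq2=s2))
                truth_rows.append({
                    "read_id": rid, "molecule_id": mol_id, "sample_id": sample,
                    "v_call": row["v_call"], "junction": row["junction"],
                    "j_call": row["j_call"],
                })
    return reads, pd.DataFrame(truth_rows)


def write_paired_fastq(reads: Sequence[SimulatedRead], path1, path2,
                       quality_char: str = "I") -> None:
    """Write mates to two FASTQ files (Sanger Phred+33, constant quality)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n{quality_char * len(r.seq1)}\n")
            f2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n{quality_char * len(r.seq2)}\n")


def reads_as_pairs(reads: Sequence[SimulatedRead], quality: int = 40):
    """Adapt simulated reads to the caller's ReadPair interface."""
    from .clonocall import ReadPair

    return [ReadPair(read_id=r.read_id, seq1=r.seq1,
                     qual1=[quality] * len(r.seq1), seq2=r.seq2,
                     qual2=[quality] * len(r.seq2)) for r in reads]
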