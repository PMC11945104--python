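"""miRNA candidate discovery: homology search, precursor folding and
stem-loop validation with miRNA* evidence.

The workflow mirrors conserved plant miRNA annotation practice: residual sRNA
reads are matched against a panel of known mature miRNAs (up to three
mismatches under an ungapped sliding comparison), candidates are located
exactly on the transcriptome, a window around each hit is folded at minimum
free energy, and the fold is accepted as an authentic precursor only if the
mature sits on one stem arm opposite a derivable star sequence with few duplex
mismatches, small asymmetric bulges, and the canonical 2-nt 3' overhang
geometry.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import RNA

from ._utils import pair_table, to_rna
from .preprocess import UniqueReadTable

MAX_HOMOLOGY_MISMATCH = 3
DUPLEX_MISMATCH_CEILING = 5
BULGE_CEILING = 3
CANDIDATE_LENGTHS = (18, 25)
FLANK_DEFAULT = 300
FLANK_LONG = 4000  # kilobase-scale precursors (miR858-like)
MAX_PAIR_SPAN = 700  # hairpins are local: cap pairing span in long windows


@dataclass
class MiRNACandidate:
    sequence: str
    family: str
    best_reference: str
    reference_mismatches: int
    counts: dict[str, int]
    tpm: dict[str, float]


@dataclass
class HairpinAnnotation:
    precursor_id: str
    transcript_id: str
    precursor_seq: str
    precursor_span: tuple[int, int]  # 1-based inclusive, window coordinates
    structure: str  # dot-bracket over precursor_seq
    mfe: float  # kcal/mol of the full folded window
    mature_span: tuple[int, int]  # window coordinates
    star_span: tuple[int, int]
    star_seq: str
    duplex_mismatches: int
    star_detected: str  # this_experiment | other_library | none


@dataclass
class ValidationResult:
    accepted: bool
    annotation: HairpinAnnotation | None = None
    reason: str | None = None


@dataclass
class IsoformRecord:
    sequence: str
    offset: int  # 5'-end shift vs the canonical mature, signed
    counts: dict[str, int]


_FAMILY_RE = re.compile(r"(miR[0-9]+)", re.IGNORECASE)


def family_of(reference_id: str) -> str:
    """Family name from a reference id, e.g. 'ath-miR398a-5p' -> 'miR398'."""
    m = _FAMILY_RE.search(reference_id)
    return m.group(1) if m else reference_id


# --------------------------------------------------------------------------
# homology search
# --------------------------------------------------------------------------


def sliding_distance(a: str, b: str, cap: int | None = None) -> int:
    """Ungapped sliding comparison between two sequences.

    At each relative offset the distance is the Hamming distance over the
    overlap plus every position of the longer footprint left unmatched
    (so two equal-length sequences at zero offset score a plain Hamming
    distance, and a length difference of d costs at least d). The minimum
    over offsets is returned. ``cap`` prunes offsets that cannot beat it.
    """
    a = to_rna(a)
    b = to_rna(b)
    la, lb = len(a), len(b)
    span = max(la, lb)
    best = span
    max_shift = span if cap is None else cap
    for off in range(-min(max_shift, lb - 1), min(max_shift, la - 1) + 1):
        s = max(0, off)
        e = min(la, off + lb)
        if e <= s:
            continue
        penalty = span - (e - s)
        if cap is not None and penalty > cap:
            continue
        ham = sum(1 for i in range(s, e) if a[i] != b[i - off])
        d = ham + penalty
        if d < best:
            best = d
    return best


def homology_search(
    residual: UniqueReadTable,
    references: Mapping[str, str],
    max_mismatch: int = MAX_HOMOLOGY_MISMATCH,
    length_range: tuple[int, int] = CANDIDATE_LENGTHS,
    totals: Mapping[str, int] | None = None,
) -> list[MiRNACandidate]:
    """Find residual reads within ``max_mismatch`` of any known mature miRNA.

    Each hit reports its best (fewest-mismatch) reference, ties broken
    lexicographically by reference id. G:U wobbles count as mismatches here:
    this is a sequence-identity comparison, not a structural one. ``totals``
    supplies the TPM denominators (defaults to the residual table's totals).
    """
    if not references:
        warnings.warn("empty reference set: no candidates can be found")
        return []

    refs = {rid: to_rna(s) for rid, s in references.items()}
    lo, hi = length_range
    seqs = [s for s in residual.sequences() if lo <= len(s) <= hi]

    # group reads by length and compare vectorized against each reference
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)

    denom = dict(totals) if totals is not None else {
        lib: int(t) for lib, t in residual.totals.items()
    }

    best: dict[str, tuple[int, str]] = {}
    for length, group in by_len.items():
        mat = np.frombuffer("".join(group).encode(), dtype="S1").reshape(len(group), length)
        for rid in sorted(refs):
            rseq = refs[rid]
            lb = len(rseq)
            rarr = np.frombuffer(rseq.encode(), dtype="S1")
            span = max(length, lb)
            for off in range(-(lb - 1), length):
                s0 = max(0, off)
                e0 = min(length, off + lb)
                if e0 <= s0:
                    continue
                penalty = span - (e0 - s0)
                if penalty > max_mismatch:
                    continue
                ham = (mat[:, s0:e0] != rarr[s0 - off:e0 - off]).sum(axis=1)
                d = ham + penalty
                hit = np.nonzero(d <= max_mismatch)[0]
                for i in hit:
                    seq = group[i]
                    cand = (int(d[i]), rid)
                    if seq not in best or cand < best[seq]:
                        best[seq] = cand

    out = []
    for seq in sorted(best):
        dist, rid = best[seq]
        counts = {lib: int(residual.counts.at[seq, lib]) for lib in residual.library_ids}
        tpm = {lib: (counts[lib] / denom[lib] * 1e6 if denom.get(lib) else 0.0)
               for lib in residual.library_ids}
        out.append(MiRNACandidate(
            sequence=seq, family=family_of(rid), best_reference=rid,
            reference_mismatches=dist, counts=counts, tpm=tpm,
        ))
    return out


# --------------------------------------------------------------------------
# transcript placement and folding
# --------------------------------------------------------------------------


def locate_on_transcripts(
    candidate: str, transcripts: Mapping[str, str]
) -> list[tuple[str, tuple[int, int], str]]:
    """All exact sense-strand occurrences: (transcript_id, 1-based span, '+')."""
    query = to_rna(candidate)
    hits = []
    for tid in transcripts:
        seq = to_rna(transcripts[tid])
        start = seq.find(query)
        while start != -1:
            hits.append((tid, (start + 1, start + len(query)), "+"))
            start = seq.find(query, start + 1)
    return hits


def extract_precursor_window(
    transcript: str, span: tuple[int, int], flank: int
) -> tuple[str, int]:
    """Window ``[span.start - flank, span.end + flank]`` clipped to the
    transcript; returns (window sequence, offset) with
    transcript_pos = window_pos + offset."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start, end = span
    if start < 1 or end > len(transcript) or start > end:
        raise ValueError(f"span {span} lies outside the transcript (length {len(transcript)})")
    w_start = max(1, start - flank)
    w_end = min(len(transcript), end + flank)
    return transcript[w_start - 1:w_end], w_start - 1


def fold_rna(sequence: str, max_bp_span: int = MAX_PAIR_SPAN) -> tuple[str, float]:
    """Minimum-free-energy secondary structure (dot-bracket, kcal/mol).

    Windows longer than ``max_bp_span`` are folded with that maximum pairing
    span: miRNA hairpins are local structures, and the cap keeps kilobase
    precursors tractable without touching the duplex of interest.
    """
    seq = to_rna(sequence)
    if not 40 <= len(seq) <= 7000:
        raise ValueError(f"sequence length {len(seq)} outside the foldable range 40-7000 nt")
    md = RNA.md()
    if len(seq) > max_bp_span:
        md.max_bp_span = max_bp_span
    fc = RNA.fold_compound(seq, md)
    structure, mfe = fc.mfe()
    return structure, float(mfe)


# --------------------------------------------------------------------------
# star derivation and hairpin validation
# --------------------------------------------------------------------------


def derive_star(structure: str, mature_span: tuple[int, int]) -> tuple[int, int]:
    """Star span implied by duplex geometry: the region pairing the mature,
    shifted +2 to give the canonical 2-nt 3' overhangs on both duplex ends.

    Unpaired mature end positions are bridged by extrapolating from the
    nearest paired position, so bulged duplexes keep a full-length star.
    """
    pt = pair_table(structure)
    ms, me = mature_span
    if ms < 1 or me > len(structure) or ms > me:
        raise ValueError("mature span outside structure")
    n_paired = sum(1 for i in range(ms, me + 1) if pt[i])
    if n_paired < 0.5 * (me - ms + 1):
        raise ValueError("insufficient pairing on the mature arm")
    i = ms
    while pt[i] == 0:
        i += 1
    j = me
    while pt[j] == 0:
        j -= 1
    star_end = pt[i] + (i - ms) + 2
    star_start = pt[j] - (me - j) + 2
    if star_start > star_end:
        raise ValueError("mature arm pairs with itself; no opposite-arm star")
    return star_start, star_end


def duplex_mismatch_count(structure: str, mature_span: tuple[int, int]) -> int:
    """Mature positions not paired into the duplex, excluding the 2-nt 3'
    overhang. The MFE engine only forms Watson-Crick and G:U pairs, so a
    wobble counts as paired (structural) here."""
    pt = pair_table(structure)
    ms, me = mature_span
    return sum(1 for i in range(ms, me - 1) if pt[i] == 0)


def _max_bulge_asymmetry(pt: list[int], mature_span: tuple[int, int]) -> int:
    ms, me = mature_span
    paired = [i for i in range(ms, me + 1) if pt[i]]
    worst = 0
    for a, b in zip(paired, paired[1:]):
        gap_m = b - a - 1
        gap_s = abs(pt[a] - pt[b]) - 1
        worst = max(worst, abs(gap_m - gap_s))
    return worst


def validate_hairpin(
    window: str,
    structure: str,
    mature_span: tuple[int, int],
    srna_reads: Iterable[str] = (),
    other_reads: Iterable[str] = (),
    max_duplex_mismatch: int = DUPLEX_MISMATCH_CEILING,
    max_bulge: int = BULGE_CEILING,
    precursor_id: str = "",
    transcript_id: str = "",
    mfe: float = float("nan"),
    trim_flank: int = 10,
) -> ValidationResult:
    """Accept or reject a folded window as an authentic miRNA precursor.

    Accepts iff (a) the mature lies entirely on one stem arm with no terminal
    loop overlap, (b) a star span can be derived on the opposite arm,
    (c) duplex mismatches (unpaired mature positions opposite the star,
    excluding the 2-nt overhang) stay within ``max_duplex_mismatch``, and
    (d) asymmetric bulges within the duplex do not exceed ``max_bulge`` nt.
    The reported precursor is trimmed to the minimal stem-loop containing
    mature and star plus ``trim_flank`` nt on each side.
    """
    window = to_rna(window)
    if len(window) != len(structure):
        raise ValueError("structure and sequence lengths differ")
    ms, me = mature_span
    if ms < 1 or me > len(window):
        raise ValueError("mature span outside window")

    pt = pair_table(structure)
    mature_positions = set(range(ms, me + 1))
    partners = [pt[i] for i in mature_positions if pt[i]]
    if len(partners) < 0.5 * len(mature_positions):
        return ValidationResult(False, reason="insufficient pairing")
    if any(p in mature_positions for p in partners):
        return ValidationResult(False, reason="loop overlap")
    sides = {p < ms for p in partners}
    if len(sides) > 1:
        return ValidationResult(False, reason="loop overlap")

    try:
        star_span = derive_star(structure, mature_span)
    except ValueError as exc:
        return ValidationResult(False, reason=str(exc))
    ss, se = star_span
    if ss < 1 or se > len(window):
        return ValidationResult(False, reason="star outside window")
    if not (se < ms or ss > me):
        return ValidationResult(False, reason="mature/star overlap")

    n_mm = duplex_mismatch_count(structure, mature_span)
    if n_mm > max_duplex_mismatch:
        return ValidationResult(False, reason=f"duplex mismatches {n_mm} exceed ceiling")
    asym = _max_bulge_asymmetry(pt, mature_span)
    if asym > max_bulge:
        return ValidationResult(False, reason=f"asymmetric bulge of {asym} nt")

    star_seq = window[ss - 1:se]
    srna_set = set(to_rna(s) for s in srna_reads)
    other_set = set(to_rna(s) for s in other_reads)
    if star_seq in srna_set:
        star_detected = "this_experiment"
    elif star_seq in other_set:
        star_detected = "other_library"
    else:
        star_detected = "none"

    p_start = max(1, min(ms, ss) - trim_flank)
    p_end = min(len(window), max(me, se) + trim_flank)
    annotation = HairpinAnnotation(
        precursor_id=precursor_id,
        transcript_id=transcript_id,
        precursor_seq=window[p_start - 1:p_end],
        precursor_span=(p_start, p_end),
        structure=structure[p_start - 1:p_end],
        mfe=mfe,
        mature_span=mature_span,
        star_span=star_span,
        star_seq=star_seq,
        duplex_mismatches=n_mm,
        star_detected=star_detected,
    )
    return ValidationResult(True, annotation=annotation)


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Random sequence with exactly the same dinucleotide composition.

    Euler-path shuffle (Altschul-Erickson): edges of the dinucleotide
    multigraph are permuted subject to a randomly chosen spanning tree of
    last-edges into the final character, then walked from the first character.
    Used as the null model for hairpin validation: shuffling destroys the
    stem-loop while preserving local composition and folding propensity.
    """
    s = list(seq)
    if len(s) < 3 or len(set(s)) < 2:
        return seq
    vertices = list(dict.fromkeys(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    while True:  # draw last-edges until they form a tree into `last`
        last_edge = {}
        for v in vertices:
            if v != last and edges[v]:
                last_edge[v] = edges[v][int(rng.integers(0, len(edges[v])))]
        ok = True
        for v in last_edge:
            seen = set()
            u = v
            while u != last and ok:
                if u in seen:
                    ok = False
                seen.add(u)
                u = last_edge.get(u, last)
                if u not in last_edge and u != last:
                    ok = False
            if not ok:
                break
        if ok:
            break

    order: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        order[v] = pool

    out = [s[0]]
    cursor = {v: 0 for v in vertices}
    u = s[0]
    for _ in range(len(s) - 1):
        nxt = order[u][cursor[u]]
        cursor[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


# --------------------------------------------------------------------------
# isoforms
# --------------------------------------------------------------------------


def collect_isoforms(
    mature: str,
    residual: UniqueReadTable,
    transcript: str,
    max_shift: int = 2,
) -> list[IsoformRecord]:
    """Residual reads mapping within +-``max_shift`` nt of the mature's span
    on its transcript (isomiRs), with signed 5'-end offsets and counts."""
    tx = to_rna(transcript)
    query = to_rna(mature)
    m_start = tx.find(query)
    if m_start == -1:
        raise ValueError("mature not located on the transcript")
    m_start += 1
    m_end = m_start + len(query) - 1

    out = []
    for seq in residual.sequences():
        if abs(len(seq) - len(query)) > 2 * max_shift:
            continue
        start = tx.find(seq)
        while start != -1:
            s1 = start + 1
            e1 = s1 + len(seq) - 1
            if abs(s1 - m_start) <= max_shift and abs(e1 - m_end) <= max_shift:
                counts = {lib: int(residual.counts.at[seq, lib])
                          for lib in residual.library_ids}
                out.append(IsoformRecord(sequence=seq, offset=s1 - m_start, counts=counts))
                break
            start = tx.find(seq, start + 1)
    out.sort(key=lambda r: (r.offset, r.sequence))
    return out


# --------------------------------------------------------------------------
# end-to-end discovery over a residual table
# --------------------------------------------------------------------------


def discover_mirnas(
    residual: UniqueReadTable,
    references: Mapping[str, str],
    transcripts: Mapping[str, str],
    max_mismatch: int = MAX_HOMOLOGY_MISMATCH,
    flank: int = FLANK_DEFAULT,
    flank_long: int = FLANK_LONG,
    long_families: Sequence[str] = ("miR858",),
    srna_reads: Iterable[str] = (),
    other_reads: Iterable[str] = (),
    totals: Mapping[str, int] | None = None,
) -> tuple[list[MiRNACandidate], list[HairpinAnnotation]]:
    """Homology search, transcript placement, folding and validation in one pass.

    ``long_families`` get the wide extraction flank (kilobase-scale
    precursors); everything else uses ``flank``. Returns accepted candidates
    and their hairpin annotations with spans mapped to transcript coordinates.
    """
    candidates = homology_search(residual, references, max_mismatch, totals=totals)
    annotations: list[HairpinAnnotation] = []
    accepted: list[MiRNACandidate] = []
    n_pre = 0
    for cand in candidates:
        hits = locate_on_transcripts(cand.sequence, transcripts)
        cand_ok = False
        for tid, span, _strand in hits:
            # known long-precursor families go straight to the wide window;
            # everything else tries the standard flank first and falls back to
            # the wide one, so kilobase-scale precursors of novel families are
            # still recovered
            if cand.family in long_families:
                flank_attempts: tuple[int, ...] = (flank_long,)
            else:
                flank_attempts = (flank, flank_long) if flank_long > flank else (flank,)
            result = None
            for use_flank in flank_attempts:
                window, offset = extract_precursor_window(transcripts[tid], span, use_flank)
                if len(window) < 40:
                    continue
                structure, mfe = fold_rna(window)
                m_span_w = (span[0] - offset, span[1] - offset)
                result = validate_hairpin(
                    window, structure, m_span_w,
                    srna_reads=srna_reads, other_reads=other_reads,
                    precursor_id=f"pre-{cand.family}-{n_pre + 1}",
                    transcript_id=tid, mfe=mfe,
                )
                if result.accepted:
                    break
            if result is None or not result.accepted:
                continue
            n_pre += 1
            ann = result.annotation
            # map window coordinates back onto the transcript
            ann.precursor_span = (ann.precursor_span[0] + offset,
                                  ann.precursor_span[1] + offset)
            ann.mature_span = (ann.mature_span[0] + offset, ann.mature_span[1] + offset)
            ann.star_span = (ann.star_span[0] + offset, ann.star_span[1] + offset)
            annotations.append(ann)
            cand_ok = True
        if cand_ok:
            accepted.append(cand)
    return accepted, annotations
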