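"""Synthetic genomes, sRNA libraries, degradome tags and qPCR tables.

Every dataset is built constructively around a :class:`SyntheticTruth` record,
so the downstream pipeline (read cleanup, homology search, hairpin validation,
genome localization, degradome target calling, expression quantification) can
be checked against exact planted ground truth.

Design notes
------------
* Hairpins are constructed, not rejection-sampled: the stem is the mature
  sequence opposite a modified reverse complement (the star arm), the loop is
  drawn from {A, C} only so it cannot base-pair internally. This guarantees the
  minimum-free-energy fold contains the designed duplex and the truth
  coordinates are exact.
* The star sequence follows miRNA/miRNA* duplex geometry: the span pairing the
  mature, shifted by +2 to give the canonical 2-nt 3' overhangs.
* Designed wobbles are G:U-compatible substitutions (structurally paired,
  sequence-divergent); designed mismatches use bases that can neither
  Watson-Crick nor wobble pair.
* All truth coordinates are 1-based inclusive on the forward strand of the
  emitted record; minus-strand genomic loci store the reverse-complemented
  mature sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import revcomp, to_dna, to_rna

# bases that can pair (WC or wobble) with the key, RNA space
_PAIRABLE = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGU") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), n)])


def _mismatch_base(rng: np.random.Generator, opposite: str) -> str:
    """A base that can neither WC- nor wobble-pair with ``opposite``."""
    choices = [b for b in "ACGU" if b not in _PAIRABLE[opposite]]
    return choices[rng.integers(0, len(choices))]


# --------------------------------------------------------------------------
# truth containers
# --------------------------------------------------------------------------


@dataclass
class GenomicPlacement:
    chromosome: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str
    identity: float  # percent matching bases vs the planted precursor
    mature_genomic: str  # reverse-complemented for minus-strand loci


@dataclass
class PlantedMiRNA:
    family: str
    name: str
    mature: str  # RNA alphabet, 5'->3'
    star: str
    transcript_id: str
    mature_span: tuple[int, int]  # 1-based inclusive on transcript
    star_span: tuple[int, int]
    precursor_span: tuple[int, int]
    loci: list[GenomicPlacement]
    duplex_mismatches: int
    duplex_wobbles: int
    is_long: bool = False


@dataclass
class PlantedTarget:
    mirna_name: str
    transcript_id: str
    window: tuple[int, int]  # binding window, 1-based inclusive
    mismatch_count: int
    wobble_count: int
    cleavage_position: int  # transcript position opposite miRNA position 10
    peak_fraction: float  # fraction of the transcript's degradome tags at the site
    designed_category: str  # "I", "II" or "III"
    decoy_position: int | None = None  # off-site dominant peak (Category II)
    decoy_fraction: float = 0.0
    background_boost: bool = False  # raised background median (Category III)


@dataclass
class SyntheticTruth:
    planted_mirnas: list[PlantedMiRNA]
    planted_targets: list[PlantedTarget]
    transcripts: dict[str, str]  # DNA alphabet
    annotation_seqs: dict[str, list[str]]  # class -> sequences (DNA)
    reference_matures: dict[str, str]  # miRBase-style homology references (RNA)
    library_design: pd.DataFrame | None = None
    ct_design: dict[str, dict[str, float]] = field(default_factory=dict)

    def mirna_by_name(self, name: str) -> PlantedMiRNA:
        for m in self.planted_mirnas:
            if m.name == name:
                return m
        raise KeyError(name)


# --------------------------------------------------------------------------
# generator configuration
# --------------------------------------------------------------------------


@dataclass
class GeneratorConfig:
    """Knobs for the planted dataset.

    Defaults emulate the magnitudes of a two-condition leaf sRNA experiment:
    mature lengths of 20-21 nt, short hairpins of 80-160 nt plus one
    kilobase-scale precursor (miR858-like precursors run from ~1.5 kb up),
    1-4 duplex mismatches per hairpin, and target duplexes with 0-6
    mismatches whose cleavage site faces miRNA positions 9-11.
    """

    n_chromosomes: int = 3
    chromosome_length: int = 20_000
    n_hairpins: int = 5
    mature_length: int = 21
    precursor_length: tuple[int, int] = (80, 160)
    n_long_precursors: int = 1
    long_precursor_length: int = 1_600
    transcript_flank: int = 150
    n_decoy_transcripts: int = 8
    decoy_length: tuple[int, int] = (500, 1_200)
    duplex_mismatch_cycle: tuple[int, ...] = (1, 2, 3, 4)
    duplex_wobbles: int = 1
    targets_per_mirna: int = 1
    target_mismatch_cycle: tuple[int, ...] = (0, 1, 2, 3, 4)
    target_wobble_cycle: tuple[int, ...] = (0, 1, 1, 0, 2)
    target_category_cycle: tuple[str, ...] = ("I", "I", "I", "II", "III")
    n_paralog_copies: int = 0
    paralog_identity: float = 97.0
    annotation_classes: Mapping[str, int] = field(
        default_factory=lambda: {"tRNA": 4, "rRNA": 3, "snRNA": 2, "snoRNA": 2, "mRNA": 5}
    )
    min_loop: int = 8
    max_loop: int = 20

    def validate(self, ) -> None:
        min_pre = 2 * self.mature_length + self.min_loop + 4
        if self.precursor_length[0] < min_pre:
            raise ValueError(
                f"precursor_length minimum {self.precursor_length[0]} is shorter than "
                f"2 x mature + loop ({min_pre} nt); a stem-loop cannot be built"
            )
        if self.n_long_precursors and self.long_precursor_length < min_pre:
            raise ValueError(
                f"long_precursor_length {self.long_precursor_length} is shorter than "
                f"2 x mature + loop ({min_pre} nt)"
            )


@dataclass
class NoiseSettings:
    """Noise model for the sRNA libraries.

    ``singleton_rate`` plants reads occurring exactly once in exactly one
    library (exercising the singleton filter); ``degradation_rate`` adds
    mRNA-breakdown fragments; ``annotation_fractions`` adds reads copied from
    tRNA/rRNA/sn(o)RNA/mRNA annotation sequences. With ``sample`` on, emitted
    counts are multinomial draws at the requested depth; off, the designed
    counts are emitted verbatim.
    """

    singleton_rate: float = 0.10
    degradation_rate: float = 0.05
    n_background: int = 1_500
    shared_fraction: float = 0.27
    annotation_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"tRNA": 0.03, "rRNA": 0.05, "snRNA": 0.004,
                                 "snoRNA": 0.004, "mRNA": 0.05}
    )
    length_weights: Mapping[int, float] = field(
        default_factory=lambda: _default_length_weights()
    )
    sample: bool = True

    @classmethod
    def off(cls) -> "NoiseSettings":
        """No singletons, no degradation/annotation reads, no count sampling."""
        return cls(singleton_rate=0.0, degradation_rate=0.0,
                   annotation_fractions={}, sample=False)


def _default_length_weights() -> dict[int, float]:
    # 15-44 nt with the canonical plant sRNA structure: 21 and 24 nt dominant.
    w = {n: 0.004 for n in range(15, 45)}
    w.update({19: 0.03, 20: 0.07, 21: 0.22, 22: 0.08, 23: 0.10, 24: 0.33, 25: 0.04})
    total = sum(w.values())
    return {n: v / total for n, v in w.items()}


# --------------------------------------------------------------------------
# genome / transcripts / hairpins
# --------------------------------------------------------------------------


def _defect_positions(mature: str, n_mismatch: int, n_wobble: int) -> tuple[list[int], list[int]]:
    """Evenly spaced designed-mismatch positions plus wobble slots.

    Defects sit away from the duplex ends and at least 2 nt apart, so each
    folds as an isolated internal loop rather than merging into one."""
    L = len(mature)
    lo, hi = 5, L - 4
    if n_mismatch:
        mism = sorted({int(round(x)) for x in np.linspace(lo, hi, n_mismatch)})
    else:
        mism = []
    wob: list[int] = []
    for i in range(lo, hi + 1):
        if len(wob) == n_wobble:
            break
        if mature[i - 1] not in _WOBBLE_PARTNER:
            continue
        if any(abs(i - j) < 2 for j in mism + wob):
            continue
        wob.append(i)
    return mism, wob


def _build_hairpin_transcript(
    rng: np.random.Generator,
    mature: str,
    precursor_len: int,
    n_mismatch: int,
    n_wobble: int,
    config: "GeneratorConfig",
    is_long: bool,
    max_attempts: int = 60,
) -> dict:
    """Construct a transcript whose MFE fold realizes the designed duplex.

    The stem is built constructively (mature opposite a modified reverse
    complement, non-self-pairing loop). Because random pads and flanks can
    occasionally offer competing pairings, the construct is folded with the
    same window and parameters the discovery stage uses, and the pads, loop
    and mismatch bases are re-drawn until the realized duplex mismatch count
    and star span match the design exactly. Deterministic under the seed.
    """
    from .discovery import (FLANK_DEFAULT, FLANK_LONG, derive_star,
                            duplex_mismatch_count, extract_precursor_window,
                            fold_rna, validate_hairpin)

    L = len(mature)
    mism_pos, wob_pos = _defect_positions(mature, n_mismatch, n_wobble)
    last_error = "no attempt made"
    for _ in range(max_attempts):
        arm = list(revcomp(mature))  # arm[j-1] pairs mature position L+1-j
        for i in mism_pos:
            arm[L - i] = _mismatch_base(rng, mature[i - 1])
        for i in wob_pos:
            arm[L - i] = _WOBBLE_PARTNER[mature[i - 1]]
        loop = _random_seq(
            rng, int(rng.integers(config.min_loop, config.max_loop + 1)), alphabet="AC")
        core = mature + loop + "".join(arm)
        spare = precursor_len - len(core)
        if spare < 4:
            raise ValueError(
                f"precursor length {precursor_len} too short for a "
                f"{L}-nt duplex with a {len(loop)}-nt loop")
        pad5_len = int(rng.integers(2, spare - 1))
        pad3_len = spare - pad5_len
        precursor = _random_seq(rng, pad5_len) + core + _random_seq(rng, pad3_len)

        flank5 = _random_seq(rng, config.transcript_flank)
        flank3 = _random_seq(rng, config.transcript_flank)
        tx = flank5 + precursor + flank3
        off = len(flank5)
        m_span = (off + pad5_len + 1, off + pad5_len + L)
        arm_start = m_span[1] + len(loop) + 1
        star_span = (arm_start + 2, arm_start + L + 1)  # +2: the 3' overhang
        star = tx[star_span[0] - 1:star_span[1]]

        if tx.count(mature) != 1 or star != tx[star_span[0] - 1:star_span[1]]:
            last_error = "mature not unique in transcript"
            continue
        window, w_off = extract_precursor_window(
            tx, m_span, FLANK_LONG if is_long else FLANK_DEFAULT)
        structure, _mfe = fold_rna(window)
        m_span_w = (m_span[0] - w_off, m_span[1] - w_off)
        if duplex_mismatch_count(structure, m_span_w) != len(mism_pos):
            last_error = "fold realized a different duplex mismatch count"
            continue
        try:
            ss, se = derive_star(structure, m_span_w)
        except ValueError as exc:
            last_error = str(exc)
            continue
        if (ss + w_off, se + w_off) != star_span:
            last_error = "fold shifted the star span"
            continue
        if not validate_hairpin(window, structure, m_span_w).accepted:
            last_error = "constructed hairpin failed validation"
            continue
        return {
            "transcript": tx,
            "mature_span": m_span,
            "star_span": star_span,
            "star": star,
            "precursor": precursor,
            "precursor_span": (off + 1, off + len(precursor)),
            "n_mismatch": len(mism_pos),
            "n_wobble": len(wob_pos),
        }
    raise RuntimeError(
        f"could not realize the designed hairpin after {max_attempts} attempts "
        f"({last_error})")


def _mutate(rng: np.random.Generator, seq: str, n: int) -> str:
    """Substitute n distinct positions with a different base."""
    s = list(seq)
    for pos in rng.choice(len(s), size=min(n, len(s)), replace=False):
        s[pos] = str(rng.choice([b for b in "ACGU" if b != s[pos]]))
    return "".join(s)


def _place_on_genome(
    rng: np.random.Generator,
    genome: dict[str, list[str]],
    occupied: dict[str, list[tuple[int, int]]],
    seq_dna: str,
    chrom_order: Sequence[str],
    slot: int,
) -> tuple[str, int, int] | None:
    """Overwrite a free slice of a chromosome with seq_dna; 1-based span."""
    n = len(seq_dna)
    chroms = list(chrom_order)
    for attempt in range(len(chroms)):
        chrom = chroms[(slot + attempt) % len(chroms)]
        clen = len(genome[chrom])
        if clen <= n + 2:
            continue
        for _ in range(200):
            start0 = int(rng.integers(0, clen - n))
            span = (start0 + 1, start0 + n)
            if all(span[1] < a or span[0] > b for a, b in occupied[chrom]):
                genome[chrom][start0:start0 + n] = list(seq_dna)
                occupied[chrom].append(span)
                return chrom, span[0], span[1]
    return None


def generate_genome_and_transcripts(
    config: GeneratorConfig, seed: int
) -> tuple[dict[str, str], dict[str, str], list[tuple], SyntheticTruth]:
    """Build a planted genome, transcript set, GFF3-style locus records and truth.

    Returns ``(genome, transcripts, annotation_records, truth)`` where
    ``annotation_records`` are ``(seqid, type, start, end, strand, attrs)``
    tuples with ``type='pre_miRNA'``, ready for :func:`curesmir.io.write_gff3`.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    L = config.mature_length

    genome = {
        f"Chr{c + 1:02d}": list(_random_seq(rng, config.chromosome_length, "ACGT"))
        for c in range(config.n_chromosomes)
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    chrom_order = list(genome)

    transcripts: dict[str, str] = {}
    planted: list[PlantedMiRNA] = []
    ann_records: list[tuple] = []

    for h in range(config.n_hairpins):
        family = f"syn-miR{901 + h}"
        name = f"{family}a"
        is_long = h < config.n_long_precursors
        if is_long:
            pre_len = config.long_precursor_length
        else:
            pre_len = int(rng.integers(config.precursor_length[0],
                                       config.precursor_length[1] + 1))
        mature = _random_seq(rng, L)
        n_mm = config.duplex_mismatch_cycle[h % len(config.duplex_mismatch_cycle)]
        built = _build_hairpin_transcript(
            rng, mature, pre_len, n_mm, config.duplex_wobbles, config,
            is_long=is_long,
        )
        precursor = built["precursor"]
        star = built["star"]
        n_mm_real = built["n_mismatch"]
        n_wob_real = built["n_wobble"]
        tid = f"TX{h + 1:04d}"
        transcripts[tid] = to_dna(built["transcript"])
        mature_span = built["mature_span"]
        star_span = built["star_span"]
        precursor_span = built["precursor_span"]

        # genomic copies: one exact locus plus optional diverged paralogs
        loci: list[GenomicPlacement] = []
        copies = [(precursor, 100.0)]
        for _ in range(config.n_paralog_copies):
            n_mut = max(1, round(len(precursor) * (1 - config.paralog_identity / 100)))
            mut = _mutate(rng, precursor, n_mut)
            ident = 100.0 * sum(a == b for a, b in zip(precursor, mut)) / len(precursor)
            copies.append((mut, ident))
        for k, (copy_seq, ident) in enumerate(copies):
            strand = "+" if (h + k) % 2 == 0 else "-"
            ins = to_dna(copy_seq) if strand == "+" else revcomp(to_dna(copy_seq))
            placed = _place_on_genome(rng, genome, occupied, ins, chrom_order, h + k)
            if placed is None:
                continue
            chrom, start, end = placed
            loci.append(GenomicPlacement(
                chromosome=chrom, start=start, end=end, strand=strand,
                identity=ident,
                mature_genomic=mature if strand == "+" else revcomp(mature),
            ))
            ann_records.append((chrom, "pre_miRNA", start, end, strand,
                                {"ID": f"{name}_locus{k}", "Name": name}))

        planted.append(PlantedMiRNA(
            family=family, name=name, mature=mature, star=star,
            transcript_id=tid, mature_span=mature_span, star_span=star_span,
            precursor_span=precursor_span, loci=loci,
            duplex_mismatches=n_mm_real, duplex_wobbles=n_wob_real,
            is_long=is_long,
        ))

    # decoy transcripts: plain random sequence, no planted structure
    for d in range(config.n_decoy_transcripts):
        n = int(rng.integers(config.decoy_length[0], config.decoy_length[1] + 1))
        transcripts[f"DECOY{d + 1:04d}"] = _random_seq(rng, n, "ACGT")

    # planted miRNA binding sites on dedicated target transcripts
    targets: list[PlantedTarget] = []
    t_idx = 0
    for m in planted:
        for _ in range(config.targets_per_mirna):
            n_mm = config.target_mismatch_cycle[t_idx % len(config.target_mismatch_cycle)]
            n_wob = config.target_wobble_cycle[t_idx % len(config.target_wobble_cycle)]
            category = config.target_category_cycle[t_idx % len(config.target_category_cycle)]
            site, mm_real, wob_real = _build_binding_site(rng, m.mature, n_mm, n_wob)
            padL = _random_seq(rng, int(rng.integers(200, 500)))
            padR = _random_seq(rng, int(rng.integers(200, 500)))
            tx = padL + site + padR
            tid = f"TGT{t_idx + 1:04d}"
            transcripts[tid] = to_dna(tx)
            s = len(padL) + 1
            window = (s, s + L - 1)
            cleave = s + L - 10  # opposite miRNA position 10
            peak_fraction = {"I": 0.5, "II": 0.12, "III": 0.0}[category]
            decoy_pos = None
            decoy_frac = 0.0
            if category == "II":
                decoy_pos = max(1, s - 100)
                decoy_frac = 0.4
            targets.append(PlantedTarget(
                mirna_name=m.name, transcript_id=tid, window=window,
                mismatch_count=mm_real, wobble_count=wob_real,
                cleavage_position=cleave, peak_fraction=peak_fraction,
                designed_category=category,
                decoy_position=decoy_pos, decoy_fraction=decoy_frac,
                background_boost=(category == "III"),
            ))
            t_idx += 1

    # annotation sequence sets (tRNA/rRNA/snRNA/snoRNA/mRNA surrogates)
    typical_len = {"tRNA": 75, "rRNA": 1500, "snRNA": 150, "snoRNA": 120, "mRNA": 900}
    annotation_seqs = {
        cls: [_random_seq(rng, typical_len.get(cls, 500), "ACGT") for _ in range(n)]
        for cls, n in config.annotation_classes.items()
    }

    # homology references emulating a miRBase-style panel: each planted mature
    # appears with 0-2 substitutions under foreign species prefixes
    references: dict[str, str] = {}
    prefixes = ("aaa", "bbb", "ccc")
    for i, m in enumerate(planted):
        for r, prefix in enumerate(prefixes[: 1 + i % 2 + 1]):
            n_sub = r  # 0, 1, 2 substitutions
            references[f"{prefix}-{m.family.split('-')[1]}a"] = _mutate(rng, m.mature, n_sub) if n_sub else m.mature

    # qPCR truth: per-gene per-condition delta-Ct vs a reference gene
    samples = ("control", "cu_day1", "cu_day2")
    ct_design = {
        m.name: {s: (0.0 if s == "control" else float(np.round(rng.uniform(-3, 3), 3)))
                 for s in samples}
        for m in planted
    }

    truth = SyntheticTruth(
        planted_mirnas=planted,
        planted_targets=targets,
        transcripts=transcripts,
        annotation_seqs=annotation_seqs,
        reference_matures=references,
        ct_design=ct_design,
    )
    genome_s = {c: "".join(s) for c, s in genome.items()}
    return genome_s, transcripts, ann_records, truth


def _build_binding_site(
    rng: np.random.Generator, mature: str, n_mismatch: int, n_wobble: int
) -> tuple[str, int, int]:
    """Transcript-sense binding window for ``mature`` with designed pairing states.

    miRNA position i (5'->3') faces window position L-i+1; positions 9-11 are
    kept perfectly paired so the planted cleavage site sits in an intact duplex.
    """
    L = len(mature)
    site = [""] * L
    candidates = [i for i in range(1, L + 1) if i not in (9, 10, 11)]
    rng.shuffle(candidates)
    mism = candidates[:n_mismatch]
    wob: list[int] = []
    for i in candidates[n_mismatch:]:
        if len(wob) == n_wobble:
            break
        if mature[i - 1] in _WOBBLE_PARTNER:
            wob.append(i)
    for i in range(1, L + 1):
        base = mature[i - 1]
        if i in mism:
            site[L - i] = _mismatch_base(rng, base)
        elif i in wob:
            site[L - i] = _WOBBLE_PARTNER[base]
        else:
            site[L - i] = _WC_PARTNER[base]
    return "".join(site), len(mism), len(wob)


# --------------------------------------------------------------------------
# sRNA libraries
# --------------------------------------------------------------------------

LIBRARY_IDS = ("control", "cu")


def generate_srna_libraries(
    truth: SyntheticTruth,
    depth: int,
    noise: NoiseSettings | None = None,
    seed: int = 0,
) -> tuple[dict[str, dict[str, int]], pd.DataFrame]:
    """Two collapsed read collections (control / Cu) plus the design table.

    The design table holds the expected per-library counts per unique read;
    with ``noise.sample`` on, emitted counts are a multinomial draw of
    ``depth`` reads per library with probabilities proportional to the design,
    so a read's expected emitted count is ``depth * design / design_total``.
    Planted singleton reads are always emitted with count exactly 1.
    """
    noise = noise or NoiseSettings()
    rng = np.random.default_rng(seed)

    if depth <= 0:
        warnings.warn("zero-depth request: returning empty libraries")
        empty = pd.DataFrame(columns=["sequence", *LIBRARY_IDS, "origin"])
        truth.library_design = empty
        return {lib: {} for lib in LIBRARY_IDS}, empty

    rows: list[tuple[str, int, int, str]] = []
    seen: set[str] = set()

    def add(seq: str, c_control: int, c_cu: int, origin: str) -> None:
        if seq in seen or len(seq) < 15:
            return
        seen.add(seq)
        rows.append((seq, int(c_control), int(c_cu), origin))

    for m in truth.planted_mirnas:
        base = float(np.exp(rng.uniform(np.log(80), np.log(3000))))
        fc = 2.0 ** rng.uniform(-2.5, 2.5)
        c_ctrl = max(2, round(base))
        c_cu = max(2, round(base * fc))
        add(m.mature, c_ctrl, c_cu, f"mature:{m.name}")
        star_frac = rng.uniform(0.02, 0.10)
        add(m.star, max(2, round(c_ctrl * star_frac)),
            max(2, round(c_cu * star_frac)), f"star:{m.name}")

    lengths = np.array(sorted(noise.length_weights))
    probs = np.array([noise.length_weights[int(n)] for n in lengths], dtype=float)
    probs /= probs.sum()

    def background_counts() -> tuple[int, int]:
        if rng.random() < noise.shared_fraction:
            return 2 + int(rng.poisson(12)), 2 + int(rng.poisson(12))
        if rng.random() < 0.5:
            return 2 + int(rng.poisson(1.2)), 0
        return 0, 2 + int(rng.poisson(1.2))

    n_annot = {cls: round(f * noise.n_background)
               for cls, f in noise.annotation_fractions.items()}
    n_plain = noise.n_background - sum(n_annot.values())
    for _ in range(max(0, n_plain)):
        n = int(rng.choice(lengths, p=probs))
        c1, c2 = background_counts()
        add(_random_seq(rng, n), c1, c2, "background")
    for cls, n_cls in n_annot.items():
        pool = truth.annotation_seqs.get(cls, [])
        for _ in range(n_cls):
            if not pool:
                break
            src = to_rna(pool[rng.integers(0, len(pool))])
            flen = int(rng.integers(18, 31))
            if len(src) <= flen:
                continue
            s0 = int(rng.integers(0, len(src) - flen))
            c1, c2 = background_counts()
            add(src[s0:s0 + flen], c1, c2, f"annotation:{cls}")

    n_degr = round(noise.degradation_rate * noise.n_background)
    tx_ids = list(truth.transcripts)
    for _ in range(n_degr):
        src = to_rna(truth.transcripts[tx_ids[rng.integers(0, len(tx_ids))]])
        flen = int(rng.integers(15, 31))
        if len(src) <= flen:
            continue
        s0 = int(rng.integers(0, len(src) - flen))
        c1, c2 = background_counts()
        add(src[s0:s0 + flen], c1, c2, "degradation")

    design = pd.DataFrame(rows, columns=["sequence", *LIBRARY_IDS, "origin"])

    libraries: dict[str, dict[str, int]] = {}
    for lib in LIBRARY_IDS:
        weights = design[lib].to_numpy(dtype=float)
        if noise.sample:
            total = weights.sum()
            counts = rng.multinomial(depth, weights / total) if total > 0 else weights
        else:
            counts = weights
        libraries[lib] = {
            seq: int(c) for seq, c in zip(design["sequence"], counts) if c > 0
        }

    # planted cross-library singletons: exactly one occurrence, one library
    n_singletons = round(noise.singleton_rate * noise.n_background)
    singleton_rows = []
    for k in range(n_singletons):
        n = int(rng.choice(lengths, p=probs))
        seq = _random_seq(rng, n)
        if seq in seen:
            continue
        seen.add(seq)
        lib = LIBRARY_IDS[k % 2]
        libraries[lib][seq] = 1
        singleton_rows.append(
            (seq, 1 if lib == "control" else 0, 1 if lib == "cu" else 0, "singleton")
        )
    if singleton_rows:
        design = pd.concat(
            [design, pd.DataFrame(singleton_rows, columns=design.columns)],
            ignore_index=True,
        )

    truth.library_design = design
    return libraries, design


# --------------------------------------------------------------------------
# degradome
# --------------------------------------------------------------------------


def generate_degradome(
    truth: SyntheticTruth,
    depth: int,
    seed: int = 0,
    libraries: Sequence[str] = ("DEG1",),
    tag_length: int = 20,
    sample: bool = True,
) -> dict[str, dict[str, int]]:
    """Collapsed degradome tag collections, one per library.

    Each tag is the ``tag_length``-nt transcript subsequence starting at the
    5'-end position of an uncapped fragment. Planted targets concentrate the
    designed fraction of their transcript's tags at the cleavage position;
    the remainder is uniform background. Category II targets carry an off-site
    dominant peak; Category III targets sit on a raised-background transcript
    whose occupied-position median exceeds the cleavage-site signal.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)

    by_tx: dict[str, list[PlantedTarget]] = {}
    for t in truth.planted_targets:
        if t.transcript_id not in truth.transcripts:
            raise ValueError(f"target transcript {t.transcript_id!r} is not in the transcript set")
        by_tx.setdefault(t.transcript_id, []).append(t)

    cells: list[tuple[str, int]] = []
    weights: list[float] = []
    for tid, seq in truth.transcripts.items():
        n_pos = len(seq) - tag_length + 1
        if n_pos < 1:
            continue
        tx_weight = 1.0 if tid in by_tx else 0.25
        pos_w = np.ones(n_pos)
        for t in by_tx.get(tid, ()):
            cleave0 = t.cleavage_position - 1
            if t.background_boost:
                # Category III: background everywhere dominates the site, but
                # the site still out-signals its window neighbours so the
                # cleavage call lands on the planted position
                pos_w[:] = 10.0
                for q in (cleave0 - 1, cleave0 + 1):
                    if 0 <= q < n_pos:
                        pos_w[q] = 1.0
                pos_w[cleave0] = 5.0
                continue
            if t.peak_fraction > 0:
                rest = pos_w.sum()
                pos_w[cleave0] += (
                    t.peak_fraction * rest / max(1e-9, 1 - t.peak_fraction - t.decoy_fraction)
                )
            if t.decoy_position is not None and t.decoy_fraction > 0:
                base = pos_w.sum()
                pos_w[t.decoy_position - 1] += t.decoy_fraction * base
        pos_w = pos_w / pos_w.sum() * tx_weight
        cells.extend((tid, p + 1) for p in range(n_pos))
        weights.extend(pos_w.tolist())

    w = np.asarray(weights)
    w /= w.sum()

    out: dict[str, dict[str, int]] = {}
    for lib in libraries:
        if sample:
            counts = rng.multinomial(depth, w)
        else:  # deterministic expected counts for exact-recovery checks
            counts = np.floor(depth * w + 0.5).astype(np.int64)
        tags: dict[str, int] = {}
        for (tid, pos), c in zip(cells, counts):
            if c == 0:
                continue
            tag = truth.transcripts[tid][pos - 1:pos - 1 + tag_length]
            tags[tag] = tags.get(tag, 0) + int(c)
        out[lib] = tags
    return out


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------


def generate_ct_table(
    ct_design: Mapping[str, Mapping[str, float]],
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    tech_replicates: int = 3,
    reference_gene: str = "reference",
    base_ct: float = 20.0,
) -> pd.DataFrame:
    """Simulated qPCR table: columns gene, sample, bio_rep, tech_rep, ct.

    ``ct_design[gene][sample]`` is the true delta-Ct of the gene versus the
    reference gene in that sample; with ``noise_sd == 0`` the designed
    2^-ddCt values are recovered exactly by the expression module.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    samples: list[str] = []
    for g in ct_design:
        for s in ct_design[g]:
            if s not in samples:
                samples.append(s)

    rows = []
    genes = list(ct_design) + [reference_gene]
    for gene in genes:
        for sample in samples:
            dct = 0.0 if gene == reference_gene else float(ct_design[gene][sample])
            for b in range(1, replicates + 1):
                for t in range(1, tech_replicates + 1):
                    ct = base_ct + dct + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                    rows.append((gene, sample, b, t, round(ct, 4)))
    return pd.DataFrame(rows, columns=["gene", "sample", "bio_rep", "tech_rep", "ct"])
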