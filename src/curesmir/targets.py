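"""Degradome-supported miRNA target confirmation.

miRNAs are slid (as reverse complements, ungapped) along transcripts to find
near-complementary binding windows, with per-position match / G-U wobble /
mismatch states tracked separately: wobbles are stable in RNA duplexes and are
conventionally not counted as mismatches. Degradome (PARE) tags are piled up
by 5'-end position and normalized to tags per ten million (TP10M); a cleavage
call is the dominant signal among the transcript positions facing miRNA
positions 9-11, and targets are ranked Category I (site is the transcript-wide
maximum), II (above the median of occupied positions), or III (the rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._utils import pair_state, to_rna

MAX_TARGET_MISMATCH = 6  # admits the weakest printed plant duplexes
CLEAVAGE_MIRNA_POSITIONS = (9, 10, 11)


@dataclass
class TargetAlignment:
    mirna_id: str
    transcript_id: str
    window: tuple[int, int]  # 1-based inclusive on the transcript
    states: str  # one char per miRNA position 5'->3': '|' match, 'o' wobble, 'x' mismatch
    mismatch_count: int
    wobble_count: int

    @property
    def match_count(self) -> int:
        return self.states.count("|")

    def transcript_position(self, mirna_position: int) -> int:
        """Transcript coordinate opposite a (1-based, 5'->3') miRNA position."""
        return self.window[1] - mirna_position + 1


@dataclass
class DegradomeProfile:
    transcript_id: str
    library_id: str
    raw: np.ndarray  # per-position 5'-end tag counts, index 0 = position 1
    total_tags: int  # raw library size (TP10M denominator)

    @property
    def tp10m(self) -> np.ndarray:
        return self.raw / self.total_tags * 1e7

    def occupied(self) -> np.ndarray:
        """Positions (1-based) holding at least one raw tag."""
        return np.nonzero(self.raw > 0)[0] + 1


@dataclass
class CleavageCall:
    alignment: TargetAlignment
    library_id: str
    window_positions: tuple[int, int, int]  # transcript positions facing miRNA 9-11
    peak_position: int
    peak_abundance: float  # TP10M
    category: str = ""


def align_mirna_target(
    mirna: str,
    transcript: str,
    transcript_id: str = "",
    mirna_id: str = "",
    max_mismatch: int = MAX_TARGET_MISMATCH,
) -> list[TargetAlignment]:
    """All ungapped binding windows with at most ``max_mismatch`` mismatches.

    The reverse complement of the miRNA is slid along the transcript sense
    strand; at each window, miRNA position i (5'->3') faces transcript
    position window_end - i + 1. G:U and U:G oppositions are wobbles, not
    mismatches. Results sort by (mismatches, wobbles, window start).
    """
    m = to_rna(mirna)
    tx = to_rna(transcript)
    L = len(m)
    n = len(tx)
    if n < L:
        return []

    tx_arr = np.frombuffer(tx.encode(), dtype="S1")
    # windows w = 0..n-L; miRNA pos i faces tx index w + L - i
    state_mat = np.empty((n - L + 1, L), dtype="U1")
    for i in range(1, L + 1):
        base = m[i - 1]
        opp = tx_arr[L - i: n - i + 1]  # aligned over window starts
        col = np.full(opp.shape, "x", dtype="U1")
        wc = {"A": b"U", "U": b"A", "G": b"C", "C": b"G"}[base]
        col[opp == wc] = "|"
        if base == "G":
            col[opp == b"U"] = "o"
        elif base == "U":
            col[opp == b"G"] = "o"
        state_mat[:, i - 1] = col

    mism = (state_mat == "x").sum(axis=1)
    wob = (state_mat == "o").sum(axis=1)
    out = []
    for w in np.nonzero(mism <= max_mismatch)[0]:
        out.append(TargetAlignment(
            mirna_id=mirna_id, transcript_id=transcript_id,
            window=(int(w) + 1, int(w) + L),
            states="".join(state_mat[w]),
            mismatch_count=int(mism[w]), wobble_count=int(wob[w]),
        ))
    out.sort(key=lambda a: (a.mismatch_count, a.wobble_count, a.window[0]))
    return out


def build_profile(
    tags: Mapping[str, int] | Iterable[str],
    transcript: str,
    library_size: int,
    transcript_id: str = "",
    library_id: str = "",
) -> DegradomeProfile:
    """Per-position degradome 5'-end pile-up on a transcript (exact matching).

    ``tags`` is a {sequence: count} mapping (or a plain iterable counting each
    occurrence once); every exact sense-strand occurrence of a tag contributes
    its count at the occurrence's 5' position. TP10M = count / library_size x 1e7.
    """
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if not isinstance(tags, Mapping):
        counted: dict[str, int] = {}
        for t in tags:
            counted[t] = counted.get(t, 0) + 1
        tags = counted
    tx = to_rna(transcript)
    raw = np.zeros(len(tx), dtype=np.int64)
    for tag, count in tags.items():
        t = to_rna(tag)
        if not t:
            continue
        pos = tx.find(t)
        while pos != -1:
            raw[pos] += count
            pos = tx.find(t, pos + 1)
    return DegradomeProfile(transcript_id=transcript_id, library_id=library_id,
                            raw=raw, total_tags=library_size)


def call_cleavage(
    alignment: TargetAlignment, profile: DegradomeProfile
) -> CleavageCall | None:
    """Cleavage site within the canonical window facing miRNA positions 9-11.

    The peak is the window position with maximal TP10M; ties resolve to the
    position facing miRNA position 10 (the canonical slicing site), then to
    the smaller coordinate. Returns None when the window holds no signal.
    """
    positions = tuple(alignment.transcript_position(i) for i in CLEAVAGE_MIRNA_POSITIONS)
    n = len(profile.raw)
    if any(p < 1 or p > n for p in positions):
        raise ValueError("cleavage window outside the degradome profile")
    tp = profile.tp10m
    abund = {p: float(tp[p - 1]) for p in positions}
    if all(v == 0.0 for v in abund.values()):
        return None
    best = max(abund.values())
    canonical = alignment.transcript_position(10)
    tied = sorted(p for p, v in abund.items() if v == best)
    peak = canonical if canonical in tied else tied[0]
    return CleavageCall(
        alignment=alignment, library_id=profile.library_id,
        window_positions=positions, peak_position=peak, peak_abundance=best,
    )


def categorize_target(call: CleavageCall, profile: DegradomeProfile) -> str:
    """Category I / II / III reliability of a cleavage call.

    Over transcript positions holding at least one raw tag: Category I iff the
    peak equals the transcript-wide maximum abundance and that maximum stands
    above the median (a flat profile whose "maximum" is everywhere carries no
    evidence); Category II iff the peak lies strictly between the median and
    the maximum; Category III otherwise.
    """
    occ = profile.occupied()
    if occ.size == 0:
        raise ValueError("empty degradome profile")
    tp = profile.tp10m
    vals = tp[occ - 1]
    maximum = float(vals.max())
    median = float(np.median(vals))
    peak = call.peak_abundance
    if peak == maximum and maximum > median:
        cat = "I"
    elif median < peak < maximum:
        cat = "II"
    else:
        cat = "III"
    call.category = cat
    return cat


@dataclass
class TargetSummary:
    mirna_id: str
    transcript_id: str
    representative: TargetAlignment
    categories: dict[str, str] = field(default_factory=dict)  # library -> category

    @property
    def best_category(self) -> str:
        order = {"I": 0, "II": 1, "III": 2}
        return min(self.categories.values(), key=lambda c: order.get(c, 9))


def summarize_targets(calls: Sequence[CleavageCall]) -> list[TargetSummary]:
    """Merge per-library cleavage calls into one record per miRNA-target pair.

    The representative alignment is the one with the fewest mismatches (ties:
    fewest wobbles, then miRNA id), matching the convention of reporting the
    best-supported family member per target.
    """
    if not calls:
        raise ValueError("at least one cleavage call is required")
    groups: dict[tuple[str, str], list[CleavageCall]] = {}
    for c in calls:
        key = (c.alignment.mirna_id, c.alignment.transcript_id)
        groups.setdefault(key, []).append(c)
    out = []
    for (mid, tid), group in sorted(groups.items()):
        rep = min(
            (c.alignment for c in group),
            key=lambda a: (a.mismatch_count, a.wobble_count, a.mirna_id),
        )
        categories = {}
        for c in group:
            if c.category:
                prev = categories.get(c.library_id)
                order = {"I": 0, "II": 1, "III": 2}
                if prev is None or order.get(c.category, 9) < order.get(prev, 9):
                    categories[c.library_id] = c.category
        out.append(TargetSummary(mirna_id=mid, transcript_id=tid,
                                 representative=rep, categories=categories))
    return out


def plot_tplot(
    profile: DegradomeProfile,
    call: CleavageCall | None = None,
    path: str | None = None,
    orf: tuple[int, int] | None = None,
):
    """t-plot: per-position TP10M along the transcript with the cleavage
    window marked; optionally shades the ORF. Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 2.6))
    tp = profile.tp10m
    ax.vlines(np.arange(1, len(tp) + 1), 0, tp, color="0.55", linewidth=0.8)
    if orf is not None:
        ax.axvspan(orf[0], orf[1], color="lightgreen", alpha=0.3, label="ORF")
    if call is not None:
        lo, hi = min(call.window_positions), max(call.window_positions)
        ax.axvspan(lo - 0.5, hi + 0.5, color="red", alpha=0.25)
        ax.annotate("", xy=(call.peak_position, call.peak_abundance),
                    xytext=(call.peak_position, call.peak_abundance * 1.2 + 1),
                    arrowprops=dict(color="red", arrowstyle="->"))
    ax.set_xlabel(f"{profile.transcript_id} position (nt)")
    ax.set_ylabel("TP10M")
    ax.set_title(f"{profile.transcript_id} [{profile.library_id}]", fontsize=9)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
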