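"""Positional RNA splicing maps.

Motif patterns are ordered alternations of IUPAC words and variable-length
spacers (``CACN{3,15}CAC`` is word-gap-word). Matching enumerates every
admissible spacer length, and "coverage" is the union of *word* positions of
all matches — spacer nucleotides are unconstrained sequence and are not
counted (configurable via ``cover_gaps``).

The splicing-map axis standardizes each cassette-exon event onto 1540
positions: the last 135 nt of the upstream constitutive exon, the first and
last 250 nt of each flanking intron, the first and last 135 nt of the
cassette exon, and the first 135 nt of the downstream constitutive exon.
Features too short to fill their segments are masked so no nucleotide is
counted twice. Enrichment versus a background exon set is assessed
position-wise with a label-permutation test.
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from typing import Sequence

import numpy as np

from .io_formats import EventTableRow, GenomeStore

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "U": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGTN",  # N in a word matches anything, including sequence N
}

# deterministic point mutation: central base swapped to one the class excludes
_MUTATION = {
    "A": "T",
    "C": "G",
    "G": "C",
    "T": "A",
    "U": "A",
    "Y": "A",
    "R": "C",
    "S": "A",
    "W": "C",
    "K": "C",
    "M": "G",
    "B": "A",
    "D": "C",
    "H": "G",
    "V": "T",
}


class MotifParseError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class Word:
    letters: str

    def __len__(self) -> int:
        return len(self.letters)


@dataclasses.dataclass(frozen=True)
class Gap:
    min: int
    max: int


Component = Word | Gap


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    """Single, bipartite or linked motif: alternation of component chains."""

    name: str
    variants: tuple[tuple[Component, ...], ...]

    def __post_init__(self):
        for chain in self.variants:
            if not chain or isinstance(chain[0], Gap) or isinstance(chain[-1], Gap):
                raise MotifParseError(
                    f"{self.name}: pattern must start and end with a word"
                )
            for comp in chain:
                if isinstance(comp, Gap) and comp.min > comp.max:
                    raise MotifParseError(f"{self.name}: gap min > max")
            if sum(len(c) for c in chain if isinstance(c, Word)) < 1:
                raise MotifParseError(f"{self.name}: empty pattern")

    def min_span(self) -> int:
        return min(
            sum(len(c) if isinstance(c, Word) else c.min for c in chain)
            for chain in self.variants
        )

    def spec_string(self) -> str:
        parts = []
        for chain in self.variants:
            s = ""
            for comp in chain:
                if isinstance(comp, Word):
                    s += comp.letters
                else:
                    s += f"N{{{comp.min},{comp.max}}}"
            parts.append(s)
        return "|".join(parts)


_TOKEN = re.compile(r"N\{(\d+),(\d+)\}|[ACGTUNRYSWKMBDHV]", re.IGNORECASE)


def parse_motif(spec: str, name: str | None = None) -> MotifPattern:
    """Parse ``WORD(N{min,max}WORD)*`` with ``|`` between full variants.

    U is normalized to T; parsing is case-insensitive. ``N`` followed by
    ``{min,max}`` is a spacer; a bare ``N`` is a word character.
    """
    variants = []
    for variant_spec in spec.split("|"):
        variant_spec = variant_spec.strip()
        chain: list[Component] = []
        pos = 0
        letters = ""
        while pos < len(variant_spec):
            m = _TOKEN.match(variant_spec, pos)
            if m is None:
                raise MotifParseError(
                    f"illegal character {variant_spec[pos]!r} at position {pos} in {spec!r}"
                )
            if m.group(1) is not None:
                if letters:
                    chain.append(Word(letters))
                    letters = ""
                chain.append(Gap(int(m.group(1)), int(m.group(2))))
            else:
                letters += m.group(0).upper().replace("U", "T")
            pos = m.end()
        if letters:
            chain.append(Word(letters))
        variants.append(tuple(chain))
    return MotifPattern(name=name or spec, variants=tuple(variants))


#: Characterized binding motifs for the four regulators under study.
PAPER_MOTIFS = {
    "RBPMS": "CACN{3,15}CAC",
    "MBNL": "YGCYN{5,20}YGCY",
    "RBFOX2": "GCATG",
    "QK": "ACTAA|CTAAC",
}


def link_patterns(
    a: MotifPattern, b: MotifPattern, spacer: tuple[int, int] = (5, 25), name: str | None = None
) -> MotifPattern:
    """Join two patterns with a variable spacer (cross-product of variants)."""
    gap = Gap(*spacer)
    variants = tuple(
        ca + (gap,) + cb for ca in a.variants for cb in b.variants
    )
    return MotifPattern(name=name or f"{a.name}-{b.name}", variants=variants)


def mutate_pattern(pattern: MotifPattern) -> MotifPattern:
    """Control pattern: point-substitute the central base of every word.

    The substituted base is excluded by the original IUPAC class
    (C→G, G→C, A→T, T/Y→A), so real sites no longer match while length and
    spacer structure are preserved. A word of all-N has nothing to exclude
    and is left unchanged with a warning.
    """
    variants = []
    for chain in pattern.variants:
        new_chain: list[Component] = []
        for comp in chain:
            if isinstance(comp, Gap):
                new_chain.append(comp)
                continue
            mid = len(comp.letters) // 2
            base = comp.letters[mid]
            if base == "N":
                warnings.warn(f"cannot mutate all-matching base in {comp.letters}")
                new_chain.append(comp)
            else:
                new_chain.append(
                    Word(comp.letters[:mid] + _MUTATION[base] + comp.letters[mid + 1 :])
                )
        variants.append(tuple(new_chain))
    return MotifPattern(name=f"{pattern.name}_mut", variants=tuple(variants))


def _word_regex(word: Word) -> re.Pattern:
    # lookahead so overlapping occurrences are all reported
    body = "".join(f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch] for ch in word.letters)
    return re.compile(f"(?=({body}))")


def _word_starts(sequence: str, word: Word) -> np.ndarray:
    return np.fromiter(
        (m.start() for m in _word_regex(word).finditer(sequence)), dtype=np.int64
    )


def _chain_covered(sequence: str, chain: tuple[Component, ...], covered: np.ndarray) -> None:
    words = [c for c in chain if isinstance(c, Word)]
    gaps = [c for c in chain if isinstance(c, Gap)]
    starts = [_word_starts(sequence, w) for w in words]
    if any(s.size == 0 for s in starts):
        return
    m = len(words)
    # forward[k]: starts of word k reachable from a chain prefix
    forward = [starts[0]]
    for k in range(1, m):
        prev = forward[k - 1]
        if prev.size == 0:
            forward.append(prev[:0])
            continue
        lo = prev + len(words[k - 1]) + gaps[k - 1].min
        hi = prev + len(words[k - 1]) + gaps[k - 1].max
        keep = np.zeros(starts[k].size, dtype=bool)
        # mark starts[k] entries falling in any [lo, hi] interval
        left = np.searchsorted(starts[k], lo, side="left")
        right = np.searchsorted(starts[k], hi, side="right")
        for l, r in zip(left, right):
            if l < r:
                keep[l:r] = True
        forward.append(starts[k][keep])
    # backward[k]: starts of word k from which a chain suffix completes
    backward = [None] * m
    backward[m - 1] = forward[m - 1]
    for k in range(m - 2, -1, -1):
        nxt = backward[k + 1]
        cand = forward[k]
        if nxt.size == 0 or cand.size == 0:
            backward[k] = cand[:0]
            continue
        lo = cand + len(words[k]) + gaps[k].min
        hi = cand + len(words[k]) + gaps[k].max
        left = np.searchsorted(nxt, lo, side="left")
        right = np.searchsorted(nxt, hi, side="right")
        backward[k] = cand[left < right]
    for k in range(m):
        w = len(words[k])
        for s in backward[k]:
            covered[s : s + w] = True


def find_matches(sequence: str, pattern: MotifPattern, cover_gaps: bool = False) -> np.ndarray:
    """Boolean array marking positions covered by any match of the pattern.

    All admissible spacer lengths at every start are enumerated (matches may
    overlap); covered positions are the union of word positions. With
    ``cover_gaps=True`` spacer positions of matches are covered too.
    """
    sequence = sequence.upper().replace("U", "T")
    covered = np.zeros(len(sequence), dtype=bool)
    if cover_gaps:
        for chain in pattern.variants:
            _chain_spans_covered(sequence, chain, covered)
        return covered
    for chain in pattern.variants:
        _chain_covered(sequence, chain, covered)
    return covered


def _chain_spans_covered(sequence: str, chain: tuple[Component, ...], covered: np.ndarray) -> None:
    # exhaustive variant for cover_gaps: cover the full span of each match
    words = [c for c in chain if isinstance(c, Word)]
    gaps = [c for c in chain if isinstance(c, Gap)]
    starts = [_word_starts(sequence, w) for w in words]
    if any(s.size == 0 for s in starts):
        return
    sets = [set(s.tolist()) for s in starts]

    def extend(pos: int, k: int, span_start: int) -> None:
        if k == len(words):
            covered[span_start:pos] = True
            return
        if k > 0:
            gap = gaps[k - 1]
            for g in range(gap.min, gap.max + 1):
                if pos + g in sets[k]:
                    extend(pos + g + len(words[k]), k + 1, span_start)
        else:
            extend(pos + len(words[0]), 1, span_start)

    for s in starts[0]:
        extend(int(s), 0, int(s))


def coverage_profile(covered: np.ndarray, window: int = 31) -> np.ndarray:
    """Per-position % of window nucleotides covered, window truncated at ends."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = covered.size
    if n == 0:
        return np.zeros(0)
    half = window // 2
    csum = np.concatenate([[0], np.cumsum(covered.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return 100.0 * (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# standardized splicing-map axis

SEGMENTS = (
    ("upstream_exon_3p", 135),
    ("upstream_intron_5p", 250),
    ("upstream_intron_3p", 250),
    ("exon_5p", 135),
    ("exon_3p", 135),
    ("downstream_intron_5p", 250),
    ("downstream_intron_3p", 250),
    ("downstream_exon_5p", 135),
)

AXIS_LENGTH = sum(length for _, length in SEGMENTS)  # 1540

SEGMENT_SLICES: dict[str, slice] = {}
_off = 0
for _name, _len in SEGMENTS:
    SEGMENT_SLICES[_name] = slice(_off, _off + _len)
    _off += _len


def segment_labels() -> np.ndarray:
    labels = np.empty(AXIS_LENGTH, dtype=object)
    for name, sl in SEGMENT_SLICES.items():
        labels[sl] = name
    return labels


@dataclasses.dataclass
class EventRegions:
    """Feature sequences of one event, in transcript orientation."""

    event_id: str
    upstream_exon: str
    upstream_intron: str
    exon: str
    downstream_intron: str
    downstream_exon: str

    def axis_sequence_and_mask(self) -> tuple[str, np.ndarray]:
        """1540-position sequence (masked slots as '.') plus validity mask."""
        seq = np.full(AXIS_LENGTH, ".", dtype="U1")
        mask = np.zeros(AXIS_LENGTH, dtype=bool)
        for name, feat, offsets in self._segment_fill():
            sl = SEGMENT_SLICES[name]
            arr = seq[sl]
            msk = mask[sl]
            for seg_pos, feat_pos in offsets:
                arr[seg_pos] = feat[feat_pos]
                msk[seg_pos] = True
        return "".join(seq), mask

    def _segment_fill(self):
        """Yield (segment name, feature seq, [(segment idx, feature idx)])."""
        ue, ui, ex, di, de = (
            self.upstream_exon,
            self.upstream_intron,
            self.exon,
            self.downstream_intron,
            self.downstream_exon,
        )
        yield "upstream_exon_3p", ue, _align_right(len(ue), 135, min(len(ue), 135))
        v = 250 if len(ui) >= 500 else len(ui) // 2
        yield "upstream_intron_5p", ui, _align_left(len(ui), 250, v)
        yield "upstream_intron_3p", ui, _align_right(len(ui), 250, v)
        v = 135 if len(ex) >= 270 else len(ex) // 2
        yield "exon_5p", ex, _align_left(len(ex), 135, v)
        yield "exon_3p", ex, _align_right(len(ex), 135, v)
        v = 250 if len(di) >= 500 else len(di) // 2
        yield "downstream_intron_5p", di, _align_left(len(di), 250, v)
        yield "downstream_intron_3p", di, _align_right(len(di), 250, v)
        yield "downstream_exon_5p", de, _align_left(len(de), 135, min(len(de), 135))


def _align_left(feat_len: int, seg_len: int, valid: int) -> list[tuple[int, int]]:
    return [(i, i) for i in range(valid)]


def _align_right(feat_len: int, seg_len: int, valid: int) -> list[tuple[int, int]]:
    return [(seg_len - valid + i, feat_len - valid + i) for i in range(valid)]


def extract_regions(event: EventTableRow, genome: GenomeStore) -> EventRegions:
    """Pull the five feature sequences of an event, strand-aware."""
    s = event.strand
    fetch = genome.fetch
    ui_start, ui_end = event.upstream_intron
    di_start, di_end = event.downstream_intron
    return EventRegions(
        event_id=event.event_id,
        upstream_exon=fetch(event.contig, event.upstream_exon_start, event.upstream_exon_end, s),
        upstream_intron=fetch(event.contig, ui_start, ui_end, s),
        exon=fetch(event.contig, event.exon_start, event.exon_end, s),
        downstream_intron=fetch(event.contig, di_start, di_end, s),
        downstream_exon=fetch(event.contig, event.downstream_exon_start, event.downstream_exon_end, s),
    )


def event_axis_profile(
    regions: EventRegions,
    pattern: MotifPattern,
    window: int = 31,
    cover_gaps: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position motif coverage (%) on the 1540 axis, with validity mask.

    Coverage is computed over each full feature (so matches are never lost
    at segment boundaries and windows truncate only at real feature ends),
    then projected onto the axis segments.
    """
    profile = np.zeros(AXIS_LENGTH)
    mask = np.zeros(AXIS_LENGTH, dtype=bool)
    feat_cache: dict[int, np.ndarray] = {}
    for name, feat, offsets in regions._segment_fill():
        if not offsets:
            continue
        key = id(feat)
        if key not in feat_cache:
            feat_cache[key] = coverage_profile(
                find_matches(feat, pattern, cover_gaps=cover_gaps), window
            )
        cov = feat_cache[key]
        sl = SEGMENT_SLICES[name]
        seg_idx = np.fromiter((o[0] for o in offsets), dtype=np.int64)
        feat_idx = np.fromiter((o[1] for o in offsets), dtype=np.int64)
        profile[sl.start + seg_idx] = cov[feat_idx]
        mask[sl.start + seg_idx] = True
    return profile, mask


def profiles_for_events(
    events: Sequence[EventTableRow],
    genome: GenomeStore,
    pattern: MotifPattern,
    window: int = 31,
    cover_gaps: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-event axis profiles into (n_events, 1540) value/mask arrays."""
    profs = np.zeros((len(events), AXIS_LENGTH))
    masks = np.zeros((len(events), AXIS_LENGTH), dtype=bool)
    for i, ev in enumerate(events):
        profs[i], masks[i] = event_axis_profile(
            extract_regions(ev, genome), pattern, window=window, cover_gaps=cover_gaps
        )
    return profs, masks


@dataclasses.dataclass
class MapProfile:
    """Position-wise map: set means, permutation p-values, significance flags."""

    test_mean: np.ndarray
    background_mean: np.ndarray
    p_enrich: np.ndarray
    p_deplete: np.ndarray
    enriched: np.ndarray
    depleted: np.ndarray
    n_test: int
    n_background: int
    test_valid: np.ndarray = None  # per-position valid-event counts
    background_valid: np.ndarray = None
    segment: np.ndarray = dataclasses.field(default_factory=segment_labels)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": np.arange(AXIS_LENGTH),
                "segment": self.segment,
                "test_mean": self.test_mean,
                "background_mean": self.background_mean,
                "p_enrich": self.p_enrich,
                "p_deplete": self.p_deplete,
                "enriched": self.enriched,
                "depleted": self.depleted,
            }
        )


def _masked_mean(value_sum, mask_sum):
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(mask_sum > 0, value_sum / np.maximum(mask_sum, 1), np.nan)


def permutation_map(
    test_profiles: np.ndarray,
    test_masks: np.ndarray,
    background_profiles: np.ndarray,
    background_masks: np.ndarray,
    n_iter: int = 1000,
    alpha: float = 0.05,
    max_background: int = 2000,
    seed: int | np.random.Generator = 0,
) -> MapProfile:
    """Position-wise enrichment/depletion of test vs background coverage.

    The observed statistic at each position is the difference of set means
    over valid (unmasked) events. The null shuffles event labels between the
    two sets (sizes preserved, ``n_iter`` permutations) and one-sided
    p-values use the +1 correction p=(b+1)/(n_iter+1). Backgrounds larger
    than ``max_background`` are seeded-downsampled first.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(test_profiles) < 2 or len(background_profiles) < 2:
        raise ValueError("need at least 2 events per set")
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is low; p-values will be coarse")
    if len(background_profiles) > max_background:
        keep = rng.choice(len(background_profiles), size=max_background, replace=False)
        keep.sort()
        background_profiles = background_profiles[keep]
        background_masks = background_masks[keep]

    tp = np.where(test_masks, test_profiles, 0.0)
    bp = np.where(background_masks, background_profiles, 0.0)
    tm = test_masks.astype(np.float64)
    bm = background_masks.astype(np.float64)

    n_test = tp.shape[0]
    all_p = np.vstack([tp, bp])
    all_m = np.vstack([tm, bm])
    total_p = all_p.sum(axis=0)
    total_m = all_m.sum(axis=0)

    def diff_for(test_psum, test_msum):
        mt = _masked_mean(test_psum, test_msum)
        mb = _masked_mean(total_p - test_psum, total_m - test_msum)
        return mt - mb

    obs = diff_for(tp.sum(axis=0), tm.sum(axis=0))

    ge = np.zeros(AXIS_LENGTH, dtype=np.int64)
    le = np.zeros(AXIS_LENGTH, dtype=np.int64)
    n_total = all_p.shape[0]
    for _ in range(n_iter):
        idx = rng.permutation(n_total)[:n_test]
        d = diff_for(all_p[idx].sum(axis=0), all_m[idx].sum(axis=0))
        with np.errstate(invalid="ignore"):
            ge += d >= obs
            le += d <= obs

    p_enrich = (ge + 1) / (n_iter + 1)
    p_deplete = (le + 1) / (n_iter + 1)
    testable = (tm.sum(axis=0) >= 1) & (bm.sum(axis=0) >= 1) & np.isfinite(obs)
    p_enrich = np.where(testable, p_enrich, np.nan)
    p_deplete = np.where(testable, p_deplete, np.nan)
    with np.errstate(invalid="ignore"):
        enriched = testable & (p_enrich <= alpha)
        depleted = testable & (p_deplete <= alpha)
    return MapProfile(
        test_mean=_masked_mean(tp.sum(axis=0), tm.sum(axis=0)),
        background_mean=_masked_mean(bp.sum(axis=0), bm.sum(axis=0)),
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        enriched=enriched,
        depleted=depleted,
        n_test=n_test,
        n_background=bp.shape[0],
        test_valid=tm.sum(axis=0).astype(np.int64),
        background_valid=bm.sum(axis=0).astype(np.int64),
    )


@dataclasses.dataclass
class Peak:
    segment: str
    start: int  # axis positions, [start, end)
    end: int
    mean_diff: float  # mean (test − background) coverage over the run, in %


def find_peaks(
    profile: MapProfile,
    min_run: int = 5,
    min_diff: float = 1.0,
    min_support: float = 0.5,
    depleted: bool = False,
) -> list[Peak]:
    """Call peaks: runs of >= min_run contiguous flagged positions within one
    segment whose mean coverage difference exceeds ``min_diff`` points.

    The magnitude floor separates genuine positional enrichment from the
    scattered sub-threshold flags that positional autocorrelation produces
    at the alpha rate, and ``min_support`` restricts calling to positions
    where at least that fraction of each set's events contributes valid
    sequence — mean differences at sparsely supported (heavily masked)
    positions are too noisy to call. Depletion peaks use the depleted flags
    with the sign reversed.
    """
    flags = profile.depleted if depleted else profile.enriched
    if profile.test_valid is not None:
        supported = (
            (profile.test_valid >= min_support * profile.n_test)
            & (profile.background_valid >= min_support * profile.n_background)
        )
        flags = flags & supported
    diff = profile.background_mean - profile.test_mean if depleted else (
        profile.test_mean - profile.background_mean
    )
    peaks = []
    for name, sl in SEGMENT_SLICES.items():
        f = np.asarray(flags[sl], dtype=bool)
        run_start = None
        for i in range(f.size + 1):
            inside = i < f.size and f[i]
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                if i - run_start >= min_run:
                    d = float(np.nanmean(diff[sl][run_start:i]))
                    if d >= min_diff:
                        peaks.append(
                            Peak(name, sl.start + run_start, sl.start + i, d)
                        )
                run_start = None
    return peaks


def rna_map(
    test_events: Sequence[EventTableRow],
    background_events: Sequence[EventTableRow],
    genome: GenomeStore,
    pattern: MotifPattern,
    window: int = 31,
    n_iter: int = 1000,
    alpha: float = 0.05,
    max_background: int = 2000,
    seed: int | np.random.Generator = 0,
    cover_gaps: bool = False,
) -> MapProfile:
    """Convenience driver: extract, scan, profile, and permutation-test."""
    tp, tm = profiles_for_events(test_events, genome, pattern, window, cover_gaps)
    bp, bm = profiles_for_events(background_events, genome, pattern, window, cover_gaps)
    return permutation_map(
        tp, tm, bp, bm, n_iter=n_iter, alpha=alpha, max_background=max_background, seed=seed
    )
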