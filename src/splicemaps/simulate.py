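"""Synthetic study generator.

Emulates the statistical structure of a two-state smooth-muscle-cell
splicing study: a differentiated (D) versus proliferative (P) splicing
program, per-RBP knockdown contrasts with replicates, binomial
junction-count noise at configurable depth, and event-sized minigene
contigs with RBP binding motifs planted in position-dependent windows
(downstream-intron placement for activated exons, upstream-intron or exonic
placement for repressed exons) on a random background.

All randomness flows from ``SimConfig.seed`` through named substreams, so
every artifact is reproducible stage by stage.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    EventTableRow,
    GenomeStore,
    write_event_table,
    write_fasta,
    write_gtf,
    write_results,
)
from .maps import IUPAC, Gap, MotifPattern, PAPER_MOTIFS, Word, parse_motif

logger = logging.getLogger(__name__)

#: Congruent fractions emulating the observed per-RBP alignment with the
#: differentiation program (tightest for RBPMS, loosest for QK).
DEFAULT_CONGRUENT = {"RBPMS": 0.986, "RBFOX2": 0.91, "MBNL": 0.87, "QK": 0.81}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named pipeline stage under one root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


@dataclasses.dataclass
class SimConfig:
    n_events: int = 500
    n_replicates: int = 3
    depth: float = 100.0  # expected informative reads per event per replicate
    rbp_names: tuple[str, ...] = ("RBPMS", "MBNL", "RBFOX2", "QK")
    program_fraction: float = 0.5  # events regulated between D and P
    regulated_fraction: float | dict[str, float] = 0.5  # of program events, per RBP
    congruent_fraction: float | dict[str, float] | None = None  # default DEFAULT_CONGRUENT
    effect_size_range: tuple[float, float] = (0.1, 0.6)  # |program ΔPSI|
    kd_slope: float | dict[str, float] = 1.0  # scaling of KD ΔPSI vs program ΔPSI
    intron_length_range: tuple[int, int] = (500, 1500)
    exon_length_range: tuple[int, int] = (60, 240)
    flank_exon_length_range: tuple[int, int] = (90, 300)
    gc_content: float = 0.5
    motif_copies: int = 3
    inc_form_len: int = 2  # two inclusion junctions per skipping junction
    skip_form_len: int = 1
    dispersion: float = 0.0  # beta-binomial phi; 0 = pure binomial counts
    motif_specs: dict[str, str] | None = None  # rbp -> pattern spec
    seed: int = 0

    def __post_init__(self):
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for frac in (self.program_fraction, *self._per_rbp(self.regulated_fraction).values(),
                     *self._congruent().values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.dispersion < 1.0:
            raise ValueError("dispersion must be in [0, 1)")

    def _per_rbp(self, value) -> dict[str, float]:
        if isinstance(value, dict):
            return {rbp: value.get(rbp, 0.0) for rbp in self.rbp_names}
        return {rbp: value for rbp in self.rbp_names}

    def _congruent(self) -> dict[str, float]:
        if self.congruent_fraction is None:
            return {rbp: DEFAULT_CONGRUENT.get(rbp, 0.9) for rbp in self.rbp_names}
        return self._per_rbp(self.congruent_fraction)

    def patterns(self) -> dict[str, MotifPattern]:
        specs = self.motif_specs or {
            rbp: PAPER_MOTIFS[rbp] for rbp in self.rbp_names if rbp in PAPER_MOTIFS
        }
        return {rbp: parse_motif(spec, name=rbp) for rbp, spec in specs.items()}


@dataclasses.dataclass
class Placement:
    pattern: str
    region: str  # downstream_intron | upstream_intron | exon
    offset: int  # 0-based offset within the feature, transcript orientation


@dataclasses.dataclass
class TruthRecord:
    event_id: str
    psi_D: float
    psi_P: float
    labels: dict[str, str]  # rbp -> activated | repressed | unregulated
    kd_dpsi: dict[str, float]  # rbp -> true PSI_D - PSI_KD
    placements: list[Placement] = dataclasses.field(default_factory=list)

    @property
    def program_dpsi(self) -> float:
        return self.psi_D - self.psi_P


def simulate_truth(config: SimConfig, rng: np.random.Generator | None = None) -> list[TruthRecord]:
    """Draw true PSIs, per-RBP regulation labels and knockdown effects.

    Concordant regulation moves the knockdown PSI toward the proliferative
    state (KD ΔPSI has the program's sign); antagonistic regulation moves it
    the other way. PSIs are clipped to [0, 1] and the realized ΔPSI (after
    clipping) defines the truth label.
    """
    if rng is None:
        rng = stage_rng(config.seed, "truth")
    if config.n_events == 0:
        warnings.warn("n_events=0: returning empty truth")
        return []
    n = config.n_events
    reg_frac = config._per_rbp(config.regulated_fraction)
    congruent = config._congruent()
    slope = config._per_rbp(config.kd_slope) if isinstance(config.kd_slope, dict) else {
        rbp: config.kd_slope for rbp in config.rbp_names
    }

    program = rng.random(n) < config.program_fraction
    lo, hi = config.effect_size_range
    magnitude = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    dpsi = np.where(program, magnitude * sign, 0.0)
    psi_p_lo = np.maximum(0.0, -dpsi) + 0.02
    psi_p_hi = np.minimum(1.0, 1.0 - dpsi) - 0.02
    psi_P = rng.uniform(psi_p_lo, psi_p_hi)
    psi_D = np.clip(psi_P + dpsi, 0.0, 1.0)

    records = []
    for i in range(n):
        records.append(
            TruthRecord(
                event_id=f"EV{i + 1:06d}",
                psi_D=float(psi_D[i]),
                psi_P=float(psi_P[i]),
                labels={},
                kd_dpsi={},
            )
        )
    for rbp in config.rbp_names:
        regulated = program & (rng.random(n) < reg_frac[rbp])
        concord = np.where(rng.random(n) < congruent[rbp], 1.0, -1.0)
        kd = np.where(regulated, concord * slope[rbp] * dpsi, 0.0)
        psi_kd = np.clip(psi_D - kd, 0.0, 1.0)
        kd = psi_D - psi_kd  # realized effect after clipping
        for i, rec in enumerate(records):
            rec.kd_dpsi[rbp] = float(kd[i])
            if kd[i] > 0:
                rec.labels[rbp] = "activated"
            elif kd[i] < 0:
                rec.labels[rbp] = "repressed"
            else:
                rec.labels[rbp] = "unregulated"
    return records


def true_psi(record: TruthRecord, condition: str) -> float:
    """True inclusion level of one event in a named contrast arm."""
    if condition == "D":
        return record.psi_D
    if condition == "P":
        return record.psi_P
    if condition.startswith("KD_"):
        rbp = condition[3:]
        if rbp not in record.kd_dpsi:
            raise KeyError(f"unknown RBP in condition {condition!r}")
        return float(np.clip(record.psi_D - record.kd_dpsi[rbp], 0.0, 1.0))
    raise KeyError(f"unknown condition {condition!r}")


def simulate_counts(
    truth: Sequence[TruthRecord],
    config: SimConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate (ijc, sjc) arrays of shape (n_events, n_replicates).

    The total informative count is Poisson(depth); inclusion reads are
    binomial with probability ψ·lI / (ψ·lI + (1−ψ)·lS) so the effective
    form lengths must be inverted to recover ψ. With ``dispersion`` > 0 the
    inclusion probability is beta-distributed around that mean
    (beta-binomial counts).
    """
    if rng is None:
        rng = stage_rng(config.seed, f"counts:{condition}")
    psi = np.array([true_psi(rec, condition) for rec in truth])
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("true PSI outside [0, 1]")
    shape = (len(truth), config.n_replicates)
    total = rng.poisson(config.depth, size=shape)
    lI, lS = config.inc_form_len, config.skip_form_len
    theta = psi * lI / (psi * lI + (1.0 - psi) * lS)
    theta = np.broadcast_to(theta[:, None], shape)
    if config.dispersion > 0:
        phi = config.dispersion
        a = theta * (1.0 - phi) / phi
        b = (1.0 - theta) * (1.0 - phi) / phi
        # guard degenerate theta in {0,1}: beta undefined, probability is fixed
        p = np.where(
            (theta <= 0) | (theta >= 1),
            theta,
            rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)),
        )
    else:
        p = theta
    ijc = rng.binomial(total, p)
    sjc = total - ijc
    return ijc, sjc


def _instantiate_pattern(
    pattern: MotifPattern, rng: np.random.Generator, gc: float
) -> str:
    """Concrete sequence matching the pattern (uniform over classes/gaps)."""
    chain = pattern.variants[rng.integers(len(pattern.variants))]
    out = []
    for comp in chain:
        if isinstance(comp, Word):
            for ch in comp.letters:
                choices = IUPAC[ch].replace("N", "") or "ACGT"
                out.append(choices[rng.integers(len(choices))])
        else:
            out.append(_random_bases(rng, int(rng.integers(comp.min, comp.max + 1)), gc))
    return "".join(out)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def synthesize_sequences(
    truth: Sequence[TruthRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenomeStore, list[EventTableRow]]:
    """One minigene contig per event, with motifs planted by truth label.

    Activated events receive ``motif_copies`` instances of the RBP's pattern
    in the proximal 250 nt of the downstream intron; repressed events in the
    distal 250 nt of the upstream intron or inside the cassette exon (random
    choice). Placements are recorded in the TruthRecord. Background matches
    are left in place — they are part of the null. Events are placed on a
    random strand. Junction counts in the returned rows are zero; they are
    filled per contrast.
    """
    if rng is None:
        rng = stage_rng(config.seed, "sequences")
    patterns = config.patterns()
    genome = GenomeStore()
    rows: list[EventTableRow] = []
    for rec in truth:
        rec.placements = []  # idempotent under re-synthesis
        flank_lo, flank_hi = config.flank_exon_length_range
        in_lo, in_hi = config.intron_length_range
        ex_lo, ex_hi = config.exon_length_range
        len_ue = int(rng.integers(flank_lo, flank_hi + 1))
        len_ui = int(rng.integers(in_lo, in_hi + 1))
        len_ex = int(rng.integers(ex_lo, ex_hi + 1))
        len_di = int(rng.integers(in_lo, in_hi + 1))
        len_de = int(rng.integers(flank_lo, flank_hi + 1))
        feats = {
            "upstream_exon": list(_random_bases(rng, len_ue, config.gc_content)),
            "upstream_intron": list(_random_bases(rng, len_ui, config.gc_content)),
            "exon": list(_random_bases(rng, len_ex, config.gc_content)),
            "downstream_intron": list(_random_bases(rng, len_di, config.gc_content)),
            "downstream_exon": list(_random_bases(rng, len_de, config.gc_content)),
        }
        planted_spans: dict[str, list[tuple[int, int]]] = {}
        for rbp, label in rec.labels.items():
            if label == "unregulated" or rbp not in patterns:
                continue
            for _ in range(config.motif_copies):
                inst = _instantiate_pattern(patterns[rbp], rng, config.gc_content)
                if label == "activated":
                    region = "downstream_intron"
                    window = min(250, len_di)
                    span_lo, span_hi = 0, window - len(inst)
                else:
                    region = "upstream_intron" if rng.random() < 0.5 else "exon"
                    if region == "upstream_intron":
                        window = min(250, len_ui)
                        span_lo, span_hi = len_ui - window, len_ui - len(inst)
                    else:
                        span_lo, span_hi = 0, len_ex - len(inst)
                if span_hi < span_lo:
                    logger.info(
                        "%s: %s too short for %s placement, skipped",
                        rec.event_id, region, rbp,
                    )
                    continue
                # planted copies must not overwrite each other: resample the
                # offset a few times, then give up (logged)
                spans = planted_spans.setdefault(region, [])
                offset = None
                for _attempt in range(10):
                    cand = int(rng.integers(span_lo, span_hi + 1))
                    if all(cand + len(inst) <= s or cand >= e for s, e in spans):
                        offset = cand
                        break
                if offset is None:
                    logger.info(
                        "%s: no free slot in %s for %s, skipped",
                        rec.event_id, region, rbp,
                    )
                    continue
                spans.append((offset, offset + len(inst)))
                feat = feats[region]
                feat[offset : offset + len(inst)] = inst
                rec.placements.append(Placement(pattern=rbp, region=region, offset=offset))
        transcript = "".join("".join(feats[k]) for k in
                             ("upstream_exon", "upstream_intron", "exon",
                              "downstream_intron", "downstream_exon"))
        strand = "+" if rng.random() < 0.5 else "-"
        total = len(transcript)
        if strand == "+":
            contig_seq = transcript
            bounds = np.cumsum([0, len_ue, len_ui, len_ex, len_di, len_de])
            ue = (int(bounds[0]), int(bounds[1]))
            ex = (int(bounds[2]), int(bounds[3]))
            de = (int(bounds[4]), int(bounds[5]))
        else:
            contig_seq = transcript[::-1].translate(str.maketrans("ACGTN", "TGCAN"))
            bounds = np.cumsum([0, len_ue, len_ui, len_ex, len_di, len_de])
            flip = lambda s, e: (total - e, total - s)
            ue = flip(int(bounds[0]), int(bounds[1]))
            ex = flip(int(bounds[2]), int(bounds[3]))
            de = flip(int(bounds[4]), int(bounds[5]))
        contig = f"ctg_{rec.event_id}"
        genome.add(contig, contig_seq)
        row = EventTableRow(
            event_id=rec.event_id,
            gene_id=f"gene_{rec.event_id}",
            contig=contig,
            strand=strand,
            exon_start=ex[0],
            exon_end=ex[1],
            upstream_exon_start=ue[0],
            upstream_exon_end=ue[1],
            downstream_exon_start=de[0],
            downstream_exon_end=de[1],
            ijc_sample1=[0] * config.n_replicates,
            sjc_sample1=[0] * config.n_replicates,
            ijc_sample2=[0] * config.n_replicates,
            sjc_sample2=[0] * config.n_replicates,
            inc_form_len=config.inc_form_len,
            skip_form_len=config.skip_form_len,
        )
        row.validate()
        rows.append(row)
    return genome, rows


def contrast_names(config: SimConfig) -> list[str]:
    return ["D_vs_P"] + [f"D_vs_KD_{rbp}" for rbp in config.rbp_names]


def contrast_rows(
    truth: Sequence[TruthRecord],
    scaffolds: Sequence[EventTableRow],
    config: SimConfig,
    contrast: str,
) -> list[EventTableRow]:
    """Fill junction counts for one contrast (sample1 = D control)."""
    cond2 = "P" if contrast == "D_vs_P" else contrast.replace("D_vs_", "")
    rng = stage_rng(config.seed, f"counts:{contrast}")
    ijc1, sjc1 = simulate_counts(truth, config, "D", rng=rng)
    ijc2, sjc2 = simulate_counts(truth, config, cond2, rng=rng)
    rows = []
    for i, scaffold in enumerate(scaffolds):
        row = dataclasses.replace(
            scaffold,
            ijc_sample1=ijc1[i].tolist(),
            sjc_sample1=sjc1[i].tolist(),
            ijc_sample2=ijc2[i].tolist(),
            sjc_sample2=sjc2[i].tolist(),
        )
        rows.append(row)
    return rows


@dataclasses.dataclass
class Study:
    """In-memory synthetic study bundle."""

    config: SimConfig
    truth: list[TruthRecord]
    genome: GenomeStore
    scaffolds: list[EventTableRow]
    contrasts: dict[str, list[EventTableRow]]


def simulate_study(config: SimConfig) -> Study:
    truth = simulate_truth(config)
    genome, scaffolds = synthesize_sequences(truth, config)
    contrasts = {
        name: contrast_rows(truth, scaffolds, config, name)
        for name in contrast_names(config)
    }
    return Study(config=config, truth=truth, genome=genome,
                 scaffolds=scaffolds, contrasts=contrasts)


def truth_records_table(truth: Sequence[TruthRecord], config: SimConfig) -> list[dict]:
    rows = []
    for rec in truth:
        row = {
            "event_id": rec.event_id,
            "psi_D": rec.psi_D,
            "psi_P": rec.psi_P,
            "program_dpsi": rec.program_dpsi,
        }
        for rbp in config.rbp_names:
            row[f"label_{rbp}"] = rec.labels[rbp]
            row[f"kd_dpsi_{rbp}"] = rec.kd_dpsi[rbp]
        row["placements"] = ";".join(
            f"{p.pattern}:{p.region}:{p.offset}" for p in rec.placements
        )
        rows.append(row)
    return rows


def emit_dataset(truth: Sequence[TruthRecord], config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full dataset: FASTA, GTF, per-contrast tables, truth, config.

    Deterministic under a fixed seed: the same config writes byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, scaffolds = synthesize_sequences(truth, config)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["gtf"] = outdir / "events.gtf"
    write_gtf(scaffolds, paths["gtf"])
    for contrast in contrast_names(config):
        rows = contrast_rows(truth, scaffolds, config, contrast)
        p = outdir / f"events_{contrast}.tsv"
        write_event_table(rows, p)
        paths[f"events_{contrast}"] = p
    paths["truth"] = outdir / "truth.tsv"
    write_results(truth_records_table(truth, config), paths["truth"])
    paths["config"] = outdir / "config.txt"
    with open(paths["config"], "w") as out:
        for field in dataclasses.fields(config):
            out.write(f"{field.name} = {getattr(config, field.name)!r}\n")
    return paths
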