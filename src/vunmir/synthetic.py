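"""Synthetic small RNA experiment with planted miRNA hairpin loci.

The generator emulates a two-genotype x two-condition deep-sequencing
design: a reference carrying planted miRNA precursors (each constructed to
pass the five hairpin annotation criteria under the bundled fold backend),
decoy expressed loci with stacked degradation fragments, embedded
contaminant loci, and four read libraries with designed per-library
abundances, genotype-specific miRNAs, drought fold changes, a 3' adapter
on every read, and contaminant/degradation/background fractions.

Everything is deterministic given the design seed, so the full pipeline
can be tested end to end against known ground truth without downloads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fold import fold
from .hairpin import CriteriaThresholds, LocalRead, evaluate_criteria, infer_star
from .preprocess import Library
from .seqs import revcomp, to_rna, write_fasta

GENOTYPES = ("IT93K503-1", "CB46")
CONDITIONS = ("control", "drought")
# classic Illumina small RNA 3' adapter
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"


class ConstructionError(RuntimeError):
    """A precursor satisfying the criteria could not be built."""


class ConfigurationError(ValueError):
    """Invalid synthetic design parameters."""


@dataclass(frozen=True)
class SyntheticDesign:
    n_mirnas: int = 20
    n_genotype_specific: int = 3
    n_drought_up: int = 5
    n_drought_down: int = 3
    drought_log2fc: float = 2.0
    library_depths: tuple[int, int, int, int] = (200_000,) * 4
    adapter: str = DEFAULT_ADAPTER
    contaminant_fraction: float = 0.25
    degradation_fraction: float = 0.15
    imprecise_fraction: float = 0.10
    star_fraction: float = 0.10
    read_length: int = 36
    mature_len_range: tuple[int, int] = (20, 24)
    abundance_range: tuple[float, float] = (100.0, 1500.0)
    regulated_min_abundance: float = 200.0
    loop_len_range: tuple[int, int] = (8, 15)
    flank_len_range: tuple[int, int] = (20, 60)
    flank_gc: float = 0.45
    ext_stem_len: int = 12
    max_star_mutations: int = 2
    n_decoys: int = 10
    decoy_hotspots: int = 4
    hotspot_spacing: int = 75
    seed: int = 7

    def validate(self) -> None:
        if self.n_mirnas <= 0:
            raise ConfigurationError("n_mirnas must be positive")
        if self.n_genotype_specific + self.n_drought_up + self.n_drought_down > self.n_mirnas:
            raise ConfigurationError("role counts exceed n_mirnas")
        for frac in (
            self.contaminant_fraction,
            self.degradation_fraction,
            self.imprecise_fraction,
            self.star_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if self.contaminant_fraction + self.degradation_fraction >= 1.0:
            raise ConfigurationError("contaminant + degradation fractions must be < 1")
        if any(d <= 0 for d in self.library_depths):
            raise ConfigurationError("library depths must be positive")
        if len(self.adapter) < 6:
            raise ConfigurationError("adapter must be at least 6 nt")


@dataclass
class PlantedMiRNA:
    id: str
    mature_seq: str  # internal DNA alphabet
    star_seq: str
    precursor_seq: str
    locus: tuple[str, int, str]  # (reference id, 0-based start, strand)
    mature_offset: int  # precursor-local
    star_interval: tuple[int, int]  # precursor-local
    abundance: np.ndarray  # expected reads per library (4,)
    genotype_specific: bool
    specific_genotype: str | None
    drought_log2fc: tuple[float, float]  # per genotype

    @property
    def mature_rna(self) -> str:
        return to_rna(self.mature_seq)


@dataclass
class GroundTruth:
    design: SyntheticDesign
    planted: list[PlantedMiRNA]
    reference: dict[str, str]
    annotations: dict[str, dict[str, str]]
    decoy_loci: list[tuple[str, int, int]]
    hotspots: list[tuple[str, int, int]]  # (reference id, start, length); read source
    contaminant_loci: list[tuple[str, int, int]]
    libraries: list[Library]

    def expected_counts(self) -> pd.DataFrame:
        data = np.vstack([p.abundance for p in self.planted])
        return pd.DataFrame(
            data, index=[p.id for p in self.planted], columns=[l.id for l in self.libraries]
        )


@dataclass
class SimulatedLibraries:
    libraries: list[Library]
    reads: list[list[str]]  # raw reads (insert + adapter, truncated) per library
    true_counts: pd.DataFrame  # realized mature-derived reads per planted miRNA
    exact_counts: pd.DataFrame  # realized reads with exactly the mature sequence


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _mutate_star(rng: np.random.Generator, star: str, mature: str, k: int) -> str:
    """Introduce k true mismatches (no wobble) away from the star ends."""
    star_l = list(star)
    n = len(star_l)
    if k == 0 or n <= 8:
        return star
    positions = rng.choice(np.arange(3, n - 3), size=min(k, n - 6), replace=False)
    for pos in positions:
        opposite = mature[n - 1 - pos] if n - 1 - pos < len(mature) else "A"
        choices = [b for b in "ACGT" if (b, opposite) not in _PAIRS and b != star_l[pos]]
        star_l[pos] = str(rng.choice(choices))
    return "".join(star_l)


def build_precursor(
    mature: str,
    design: SyntheticDesign,
    rng: np.random.Generator,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    max_tries: int = 40,
) -> tuple[str, int, tuple[int, int], str]:
    """Construct a precursor whose hairpin passes all five criteria under the
    bundled fold backend.

    The opposite arm is the reverse complement of the mature with up to
    ``max_star_mutations`` mismatches, joined by an unstructured loop; a
    perfectly pairing stem extension flanks the duplex and random
    low-complementarity flanks pad the precursor to natural length.
    Returns (precursor, mature offset, star interval, star sequence).
    """
    if not design.mature_len_range[0] <= len(mature) <= design.mature_len_range[1]:
        raise ConstructionError(f"mature length {len(mature)} outside range")
    for _ in range(max_tries):
        loop = "".join(rng.choice(["A", "C"], size=rng.integers(*design.loop_len_range)))
        ext = _random_seq(rng, design.ext_stem_len, 0.6)
        # at least one duplex mismatch, so the mature never maps exactly onto
        # the star arm (a perfect inverted repeat would map on both strands)
        n_mut = int(rng.integers(1, max(design.max_star_mutations, 1) + 1))
        star_core = _mutate_star(rng, revcomp(mature), mature, n_mut)
        mature_on_5p = bool(rng.integers(0, 2))
        if mature_on_5p:
            core = ext + mature + loop + star_core + revcomp(ext)
            mature_off_core = len(ext)
        else:
            core = ext + star_core + loop + mature + revcomp(ext)
            mature_off_core = len(ext) + len(star_core) + len(loop)
        flank5 = _random_seq(rng, int(rng.integers(*design.flank_len_range)), design.flank_gc)
        flank3 = _random_seq(rng, int(rng.integers(*design.flank_len_range)), design.flank_gc)
        precursor = flank5 + core + flank3
        mature_off = len(flank5) + mature_off_core
        if precursor.count(mature) != 1:
            continue
        fr = fold(precursor)
        mature_iv = (mature_off, mature_off + len(mature))
        star_iv = infer_star(fr, mature_iv)
        if star_iv is None:
            continue
        # nominal clean read stack: mature and star reads, all sense
        stack = (
            LocalRead(mature_iv[0], mature_iv[1], True, 10),
            LocalRead(star_iv[0], star_iv[1], True, 2),
        )
        crit, _ = evaluate_criteria(fr, mature_iv, stack, thresholds, star_iv)
        if crit.overall:
            star_seq = precursor[star_iv[0] : star_iv[1]]
            return precursor, mature_off, star_iv, star_seq
    raise ConstructionError(f"no criteria-passing precursor after {max_tries} tries")


def _annotation_sets(rng: np.random.Generator) -> dict[str, dict[str, str]]:
    spec = {
        "rRNA": (3, 1500),
        "tRNA": (8, 80),
        "snRNA": (4, 150),
        "snoRNA": (4, 110),
        "repeats": (3, 400),
    }
    out: dict[str, dict[str, str]] = {}
    for name, (n, length) in spec.items():
        out[name] = {f"{name}_{i + 1}": _random_seq(rng, length) for i in range(n)}
    return out


def design_truth(design: SyntheticDesign | None = None) -> GroundTruth:
    """Lay out the planted miRNAs, their expression design, the synthetic
    reference, decoy loci and contaminant sets.  Deterministic given seed."""
    design = design or SyntheticDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)

    libraries = [
        Library("IT_C", GENOTYPES[0], "control"),
        Library("IT_D", GENOTYPES[0], "drought"),
        Library("CB_C", GENOTYPES[1], "control"),
        Library("CB_D", GENOTYPES[1], "drought"),
    ]

    planted: list[PlantedMiRNA] = []
    lo, hi = design.abundance_range
    matures_seen: set[str] = set()
    for i in range(design.n_mirnas):
        while True:
            m_len = int(rng.integers(design.mature_len_range[0], design.mature_len_range[1] + 1))
            mature = _random_seq(rng, m_len)
            if mature not in matures_seen and len(set(mature)) >= 3:
                matures_seen.add(mature)
                break
        precursor, off, star_iv, star_seq = build_precursor(mature, design, rng)

        if i < design.n_genotype_specific:
            role, fc = "specific", (0.0, 0.0)
        elif i < design.n_genotype_specific + design.n_drought_up:
            role, fc = "up", (design.drought_log2fc, design.drought_log2fc)
        elif i < design.n_genotype_specific + design.n_drought_up + design.n_drought_down:
            role, fc = "down", (-design.drought_log2fc, -design.drought_log2fc)
        else:
            role, fc = "flat", (0.0, 0.0)

        base_lo = design.regulated_min_abundance if role in ("up", "down") else lo
        base = float(np.exp(rng.uniform(np.log(base_lo), np.log(hi))))
        counts = np.array(
            [base, base * 2 ** fc[0], base, base * 2 ** fc[1]], dtype=float
        )
        specific_genotype = None
        if role == "specific":
            g = int(rng.integers(0, 2))
            specific_genotype = GENOTYPES[g]
            off_level = float(rng.integers(0, 3))
            if g == 0:
                counts[2:] = off_level
            else:
                counts[:2] = off_level
        planted.append(
            PlantedMiRNA(
                id=f"planted{i + 1:03d}",
                mature_seq=mature,
                star_seq=star_seq,
                precursor_seq=precursor,
                locus=("", -1, "+"),  # placed below
                mature_offset=off,
                star_interval=star_iv,
                abundance=counts,
                genotype_specific=role == "specific",
                specific_genotype=specific_genotype,
                drought_log2fc=fc,
            )
        )

    # assemble the reference: precursors, decoys and contaminant copies,
    # separated by >600 nt of random sequence so 300-nt candidate windows
    # from neighbouring loci can never overlap into one region
    annotations = _annotation_sets(rng)
    contig: list[str] = []
    pos = 0
    decoy_loci: list[tuple[str, int, int]] = []
    hotspots: list[tuple[str, int, int]] = []
    contaminant_loci: list[tuple[str, int, int]] = []
    rid = "contig1"

    def emit(seq: str) -> int:
        nonlocal pos
        start = pos
        contig.append(seq)
        pos += len(seq)
        gap = _random_seq(rng, int(rng.integers(620, 720)))
        contig.append(gap)
        pos += len(gap)
        return start

    for p in planted:
        strand = "+" if rng.integers(0, 2) else "-"
        seq = p.precursor_seq if strand == "+" else revcomp(p.precursor_seq)
        start = emit(seq)
        p.locus = (rid, start, strand)

    decoy_len = design.hotspot_spacing * design.decoy_hotspots + 40
    for d in range(design.n_decoys):
        seq = _random_seq(rng, decoy_len)
        start = emit(seq)
        decoy_loci.append((rid, start, start + decoy_len))
        for h in range(design.decoy_hotspots):
            hpos = start + 20 + h * design.hotspot_spacing
            hlen = int(rng.integers(18, 27))
            hotspots.append((rid, hpos, hlen))

    for name in ("rRNA", "tRNA"):
        for sid, seq in list(annotations[name].items())[:2]:
            start = emit(seq)
            contaminant_loci.append((rid, start, start + len(seq)))

    reference = {rid: "".join(contig)}
    return GroundTruth(
        design=design,
        planted=planted,
        reference=reference,
        annotations=annotations,
        decoy_loci=decoy_loci,
        hotspots=hotspots,
        contaminant_loci=contaminant_loci,
        libraries=libraries,
    )


_SHIFTS = np.array([-2, -1, 0, 1, 2])
_SHIFT_P = np.array([0.05, 0.20, 0.50, 0.20, 0.05])


def simulate_libraries(
    truth: GroundTruth, design: SyntheticDesign | None = None
) -> SimulatedLibraries:
    """Draw the four read libraries from the ground truth.

    Per library the read composition is one multinomial draw over planted
    matures, their stars, contaminant fragments, degradation fragments and
    random background, so each planted mature's read count is binomial with
    its designed expectation.  An adapter is appended to every read before
    truncation to the instrument read length."""
    design = design or truth.design
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    n = len(truth.planted)
    n_libs = len(truth.libraries)
    depths = design.library_depths

    ann_pool = [s for sets in truth.annotations.values() for s in sets.values()]
    ann_weights = np.array([len(s) for s in ann_pool], dtype=float)
    ann_weights /= ann_weights.sum()

    reads_per_lib: list[list[str]] = []
    true_counts = np.zeros((n, n_libs), dtype=int)
    exact_counts = np.zeros((n, n_libs), dtype=int)

    for l, depth in enumerate(depths):
        probs = np.zeros(2 * n + 3)
        for i, p in enumerate(truth.planted):
            probs[i] = p.abundance[l] / depth
            probs[n + i] = design.star_fraction * p.abundance[l] / depth
        probs[2 * n] = design.contaminant_fraction
        probs[2 * n + 1] = design.degradation_fraction
        remainder = 1.0 - probs.sum()
        if remainder < 0:
            raise ConfigurationError("designed abundances exceed library depth")
        probs[2 * n + 2] = remainder
        counts = rng.multinomial(depth, probs)

        inserts: list[str] = []
        for i, p in enumerate(truth.planted):
            n_mat = counts[i]
            true_counts[i, l] = n_mat
            n_imp = rng.binomial(n_mat, design.imprecise_fraction)
            exact_counts[i, l] = n_mat - n_imp
            inserts.extend([p.mature_seq] * (n_mat - n_imp))
            m0, m1 = p.mature_offset, p.mature_offset + len(p.mature_seq)
            for _ in range(n_imp):
                d5 = d3 = 0
                while d5 == 0 and d3 == 0:
                    d5 = int(rng.choice(_SHIFTS, p=_SHIFT_P))
                    d3 = int(rng.choice(_SHIFTS, p=_SHIFT_P))
                s0 = max(0, m0 + d5)
                s1 = min(len(p.precursor_seq), m1 + d3)
                inserts.append(p.precursor_seq[s0:s1])
            s0, s1 = p.star_interval
            inserts.extend([p.precursor_seq[s0:s1]] * counts[n + i])

        ref = truth.reference
        for _ in range(counts[2 * n]):  # contaminants
            src = ann_pool[int(rng.choice(len(ann_pool), p=ann_weights))]
            flen = int(rng.integers(18, 27))
            start = int(rng.integers(0, max(1, len(src) - flen)))
            inserts.append(src[start : start + flen])
        n_degr = counts[2 * n + 1]
        n_hot = int(round(n_degr * 0.95))
        for _ in range(n_hot):  # stacked decoy fragments
            rid_, hpos, hlen = truth.hotspots[int(rng.integers(0, len(truth.hotspots)))]
            inserts.append(ref[rid_][hpos : hpos + hlen])
        for _ in range(n_degr - n_hot):  # thin precursor degradation
            p = truth.planted[int(rng.integers(0, n))]
            flen = int(rng.integers(18, 27))
            start = int(rng.integers(0, max(1, len(p.precursor_seq) - flen)))
            inserts.append(p.precursor_seq[start : start + flen])
        for _ in range(counts[2 * n + 2]):  # unmappable background
            inserts.append(_random_seq(rng, int(rng.integers(18, 27))))

        order = rng.permutation(len(inserts))
        lib_reads = [
            (inserts[k] + design.adapter)[: design.read_length] for k in order
        ]
        reads_per_lib.append(lib_reads)

    lib_ids = [lib.id for lib in truth.libraries]
    mir_ids = [p.id for p in truth.planted]
    return SimulatedLibraries(
        libraries=list(truth.libraries),
        reads=reads_per_lib,
        true_counts=pd.DataFrame(true_counts, index=mir_ids, columns=lib_ids),
        exact_counts=pd.DataFrame(exact_counts, index=mir_ids, columns=lib_ids),
    )


def write_outputs(truth: GroundTruth, sim: SimulatedLibraries, outdir) -> None:
    """Write the reference FASTA, annotation FASTAs, per-library FASTQ files
    (uniform quality) and ground-truth TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fa", truth.reference.items())
    for name, seqs in truth.annotations.items():
        write_fasta(outdir / f"annotation_{name}.fa", seqs.items())
    write_fasta(
        outdir / "planted_precursors.fa",
        ((p.id, p.precursor_seq) for p in truth.planted),
    )
    write_fasta(
        outdir / "planted_matures.fa", ((p.id, p.mature_rna) for p in truth.planted)
    )
    for lib, reads in zip(sim.libraries, sim.reads):
        with open(outdir / f"{lib.id}.fastq", "w") as fh:
            for k, read in enumerate(reads):
                fh.write(f"@{lib.id}_{k}\n{read}\n+\n{'I' * len(read)}\n")
    truth.expected_counts().to_csv(outdir / "expected_counts.tsv", sep="\t")
    sim.true_counts.to_csv(outdir / "true_counts.tsv", sep="\t")
    planted_rows = [
        {
            "id": p.id,
            "mature": p.mature_rna,
            "reference": p.locus[0],
            "start": p.locus[1],
            "strand": p.locus[2],
            "genotype_specific": p.specific_genotype or "",
            "log2fc_IT": p.drought_log2fc[0],
            "log2fc_CB": p.drought_log2fc[1],
        }
        for p in truth.planted
    ]
    pd.DataFrame(planted_rows).to_csv(outdir / "planted.tsv", sep="\t", index=False)
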