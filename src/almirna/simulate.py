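"""Synthetic small-RNA experiment generator with full ground truth.

Emulates the study design the downstream analysis expects: two barley
genotypes (Al-tolerant wild accession ``XZ29`` and Al-sensitive cultivar
``GP``), each under control and Al treatment with two replicates — eight
libraries in all — plus one pooled degradome library.  miRNA loci of three
classes (known, new member of a known precursor, and novel candidate) are
planted in a random genome, contaminant classes (Rfam-style ncRNA, mRNA,
repeats, junk, adapter/length failures) are spiked at configurable
fractions, and per-library counts follow a negative binomial with
configurable dispersion (dispersion 0 means exact expected counts).

Genotype-exclusive miRNAs are encoded by an Al-response factor of 0 for the
absent genotype; a factor f > 0 multiplies the baseline mean in that
genotype's Al libraries, so the true log2 fold change is log2(f).

Every planted precursor is verified at generation time to fold into a
single hairpin passing all ten structure criteria; generation retries with
fresh random sequence until it does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import fold as _fold
from .io import revcomp
from .preprocess import is_junk

__all__ = [
    "SimulationConfig",
    "PlantedLocus",
    "TargetPair",
    "GroundTruth",
    "default_design",
    "make_genome",
    "make_references",
    "simulate_libraries",
    "simulate_degradome",
    "simulate_experiment",
]

GENOTYPES = ("GP", "XZ29")
TREATMENTS = ("control", "Al")

#: 3' adapter of the TruSeq small-RNA protocol
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def default_design() -> List[Tuple[str, str, int]]:
    return [
        (g, t, r) for g in GENOTYPES for t in TREATMENTS for r in (1, 2)
    ]


def library_id(genotype: str, treatment: str, replicate: int) -> str:
    return f"{genotype}_{treatment}_{replicate}"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment.

    ``effect_map`` maps miRNA name -> {genotype: factor}; factor 0 encodes
    genotype-exclusive absence (zero reads in both conditions of that
    genotype), factor f > 0 multiplies the Al-treated mean.  When None, a
    default map mixing strong responders (f = 4 or 0.25), unchanged
    (f = 1) and genotype-exclusive miRNAs is generated.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_known: int = 10
    n_new_member: int = 5
    n_candidate: int = 5
    n_contaminant_families: Dict[str, int] = field(
        default_factory=lambda: {"rfam": 8, "mrna": 8, "repeat": 4}
    )
    library_depth: int = 1_000_000
    read_length: int = 50
    adapter: str = DEFAULT_ADAPTER
    design: List[Tuple[str, str, int]] = field(default_factory=default_design)
    effect_map: Optional[Dict[str, Dict[str, float]]] = None
    dispersion: float = 0.1
    #: read-budget fractions per contaminant bin; the remainder is valid
    fractions: Dict[str, float] = field(
        default_factory=lambda: {
            "adapter_fail": 0.20,
            "short": 0.05,
            "junk": 0.01,
            "rfam": 0.12,
            "mrna": 0.20,
            "repeat": 0.002,
        }
    )
    #: distinct read species per contaminant bin
    n_species: Dict[str, int] = field(
        default_factory=lambda: {
            "adapter_fail": 50,
            "short": 30,
            "junk": 12,
            "rfam": 120,
            "mrna": 200,
            "repeat": 25,
        }
    )
    #: non-miRNA valid genome fragments (exercise the candidate-rejection path)
    n_filler_tags: int = 8
    n_target_transcripts: int = 10
    transcript_length: int = 500
    degradome_reads_per_transcript: int = 1000
    degradome_signal_fraction: float = 0.5
    degradome_read_length: int = 20
    sequencing_error_rate: float = 0.0

    def validate(self) -> None:
        if len(self.design) != 8 or set(self.design) != set(default_design()):
            raise ValueError("design must hold exactly the 8 genotype x treatment x replicate libraries")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if not self.adapter or len(set(self.adapter)) < 2:
            raise ValueError("adapter must be non-empty and non-degenerate")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if sum(self.fractions.values()) >= 1.0:
            raise ValueError("contaminant fractions must leave room for valid reads")
        if self.effect_map is not None:
            for name, per_g in self.effect_map.items():
                for g, f in per_g.items():
                    if not np.isfinite(f) or f < 0:
                        raise ValueError(f"effect factor for {name}/{g} must be finite and >= 0")

    @property
    def libraries(self) -> List[str]:
        return [library_id(*d) for d in self.design]


@dataclass
class PlantedLocus:
    name: str
    class_label: str  # known | new_member | candidate
    mature_seq: str
    precursor_seq: str
    mature_span: Tuple[int, int]  # 1-based inclusive on precursor
    arm: str  # '5p' | '3p'
    chrom: str = "chr1"
    start: int = 0  # 1-based inclusive genome coords of the precursor
    end: int = 0
    strand: str = "+"
    structure: Optional[_fold.HairpinStructure] = None
    metrics: Optional[_fold.FoldMetrics] = None


@dataclass
class TargetPair:
    mirna: str
    transcript_id: str
    site_start: int  # 1-based inclusive on transcript
    site_end: int
    cleavage_pos: int  # transcript base paired to miRNA position 10
    mismatches: int


@dataclass
class GroundTruth:
    config: SimulationConfig
    loci: List[PlantedLocus]
    genome: str = ""
    baselines: Dict[str, float] = field(default_factory=dict)
    effect_map: Dict[str, Dict[str, float]] = field(default_factory=dict)
    expected_counts: Optional[pd.DataFrame] = None  # rows: read species
    transcripts: List[Tuple[str, str]] = field(default_factory=list)
    target_pairs: List[TargetPair] = field(default_factory=list)

    def locus(self, name: str) -> PlantedLocus:
        return next(l for l in self.loci if l.name == name)

    def expected_fc(self, name: str, genotype: str):
        """True log2 fold change, or 'absent'/'exclusive' sentinels-as-strings."""
        f = self.effect_map[name][genotype]
        if f == 0:
            return "absent"
        return float(np.log2(f))

    def responsive_truth(self) -> set:
        """Apply the responsiveness rules to noise-free expectations.

        Rule 1: max expected CPM over the four conditions > 100; rule 2:
        MFEI > 0.85 for candidate-class loci; rule 3: |log2 f| >= 0.5 in at
        least one genotype where the miRNA is present.
        """
        out = set()
        valid_total = self._expected_valid_total()
        for loc in self.loci:
            base = self.baselines[loc.name]
            cpms = []
            rule3 = False
            for g in GENOTYPES:
                f = self.effect_map[loc.name][g]
                if f == 0:
                    continue
                cpms += [base / valid_total * 1e6, base * f / valid_total * 1e6]
                if abs(np.log2(f)) >= 0.5:
                    rule3 = True
            if not cpms or max(cpms) <= 100:
                continue
            if loc.class_label == "candidate" and (
                loc.metrics is None or loc.metrics.mfei <= 0.85
            ):
                continue
            if rule3:
                out.add(loc.name)
        return out

    def _expected_valid_total(self) -> float:
        frac_other = sum(self.config.fractions.values())
        return self.config.library_depth * (1.0 - frac_other)


# ---------------------------------------------------------------------------
# Sequence construction helpers

_LOOP_SEQ = "CAACAACA"  # weakly pairing terminal loop


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_mature(rng: np.random.Generator, length: int) -> str:
    for _ in range(100):
        s = _random_seq(rng, length, gc=rng.uniform(0.45, 0.6))
        if not is_junk(s):
            return s
    raise RuntimeError("could not draw a non-junk mature sequence")


def _build_hairpin(rng: np.random.Generator, mature: str, arm: str):
    """Perfect-stem hairpin: ext5 + arm + loop + revcomp(arm-side).

    Returns (precursor, mature_span, structure, metrics) with all ten
    criteria verified; raises after repeated failures.
    """
    for _ in range(50):
        ext_a = _random_seq(rng, 6, gc=0.55)
        ext_b = _random_seq(rng, 6, gc=0.55)
        arm5 = ext_a + (mature if arm == "5p" else revcomp(mature)) + ext_b
        pre = arm5 + _LOOP_SEQ + revcomp(arm5)
        if arm == "5p":
            span = (len(ext_a) + 1, len(ext_a) + len(mature))
        else:
            # mature sits on the 3' arm, reverse-complement of the embedded copy
            off = len(ext_b)  # distance from 3' arm start
            start = len(arm5) + len(_LOOP_SEQ) + off + 1
            span = (start, start + len(mature) - 1)
        st = _fold.fold(pre)
        rep = _fold.check_criteria(st, span)
        if rep.passed:
            met = _fold.fold_metrics(st)
            if met.mfei > 0.85:
                return pre, span, st, met
    raise RuntimeError("failed to construct a criteria-passing hairpin")


# ---------------------------------------------------------------------------
# Stage 1: genome and loci


def make_genome(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Build the random genome with planted hairpin loci.

    Returns (genome_sequence, GroundTruth) where the truth holds every
    planted locus with exact genome coordinates; loci are separated by at
    least 240 nt so 120-nt flank windows never span two loci.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n_loci = config.n_known + config.n_new_member + config.n_candidate
    classes = (
        ["known"] * config.n_known
        + ["new_member"] * config.n_new_member
        + ["candidate"] * config.n_candidate
    )
    loci: List[PlantedLocus] = []
    counters = {"known": 0, "new_member": 0, "candidate": 0}
    for cl in classes:
        counters[cl] += 1
        k = counters[cl]
        name = {
            "known": f"hvu-miR-k{k:02d}",
            "new_member": f"hvu-MIR-n{k:02d}",
            "candidate": f"PC-sim{k:02d}",
        }[cl]
        # 21 nt dominates known/new members; candidates are mostly 24 nt
        if cl == "candidate":
            length = int(rng.choice([23, 24, 24, 24]))
        else:
            length = int(rng.choice([20, 21, 21, 21, 22, 24]))
        mature = _random_mature(rng, length)
        arm = str(rng.choice(["5p", "3p"]))
        pre, span, st, met = _build_hairpin(rng, mature, arm)
        loci.append(
            PlantedLocus(name, cl, mature, pre, span, arm, structure=st, metrics=met)
        )

    footprint = sum(len(l.precursor_seq) for l in loci) + 400 * (n_loci + 1)
    if config.genome_length < footprint:
        raise ValueError(
            f"genome_length {config.genome_length} too short for {n_loci} loci "
            f"(need >= {footprint})"
        )
    genome = list(_random_seq(rng, config.genome_length, gc=0.45))
    pos = 0
    gap = (config.genome_length - sum(len(l.precursor_seq) for l in loci)) // (n_loci + 1)
    for loc in loci:
        pos += gap
        strand = str(rng.choice(["+", "-"]))
        insert = loc.precursor_seq if strand == "+" else revcomp(loc.precursor_seq)
        genome[pos : pos + len(insert)] = list(insert)
        loc.start, loc.end, loc.strand = pos + 1, pos + len(insert), strand
        pos += len(insert)
    genome_s = "".join(genome)
    # planted loci must be re-locatable exactly once at their coordinates
    for loc in loci:
        oriented = loc.precursor_seq if loc.strand == "+" else revcomp(loc.precursor_seq)
        if genome_s.count(oriented) != 1 or genome_s.find(oriented) != loc.start - 1:
            raise RuntimeError(f"planted locus {loc.name} is not uniquely re-locatable")
        # the mature (or its star complement) must not recur outside the locus
        for q in (loc.mature_seq, revcomp(loc.mature_seq)):
            p = genome_s.find(q)
            while p >= 0:
                if not (loc.start - 1 <= p and p + len(q) <= loc.end):
                    raise RuntimeError(f"mature of {loc.name} recurs outside its locus")
                p = genome_s.find(q, p + 1)
    truth = GroundTruth(config=config, loci=loci, genome=genome_s)
    return genome_s, truth


# ---------------------------------------------------------------------------
# Stage 2: reference sets


_XS_PREFIXES = ["ata", "osa", "tae", "bdi"]


def make_references(truth: GroundTruth, rng: Optional[np.random.Generator] = None):
    """Mature/precursor miRNA references plus contaminant FASTAs.

    Known matures go into the mature reference (a few as cross-species
    entries carrying up to 2 mismatches); new-member precursors go into the
    precursor reference only; candidate loci appear in neither.  Returns a
    dict of reference name -> list[(id, sequence)].
    """
    cfg = truth.config
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    mature_ref: List[Tuple[str, str]] = []
    precursor_ref: List[Tuple[str, str]] = []
    for loc in truth.loci:
        if loc.class_label not in ("known", "new_member", "candidate"):
            raise ValueError(f"unknown class label {loc.class_label!r}")
        if loc.class_label == "known":
            seq = loc.mature_seq
            name = loc.name
            if rng.random() < 0.3:  # cross-species homolog with <=2 mismatches
                n_mm = int(rng.integers(1, 3))
                pos = rng.choice(np.arange(2, len(seq) - 2), size=n_mm, replace=False)
                s = list(seq)
                for p in pos:
                    s[p] = str(rng.choice([c for c in "ACGT" if c != s[p]]))
                seq = "".join(s)
                name = f"{rng.choice(_XS_PREFIXES)}-{loc.name.split('-', 1)[1]}"
            mature_ref.append((name, seq))
            precursor_ref.append((f"{loc.name}-pre", loc.precursor_seq))
        elif loc.class_label == "new_member":
            precursor_ref.append((f"{loc.name}-pre", loc.precursor_seq))

    refs = {"mature": mature_ref, "precursor": precursor_ref}
    sizes = {"rfam": (100, 300), "mrna": (300, 800), "repeat": (150, 300)}
    for klass, (lo, hi) in sizes.items():
        n = truth.config.n_contaminant_families.get(klass, 0)
        entries = []
        for k in range(1, n + 1):
            length = int(rng.integers(lo, hi + 1))
            entries.append((f"{klass}{k:02d}", _random_seq(rng, length, gc=0.5)))
        refs[klass] = entries
    return refs


# ---------------------------------------------------------------------------
# Stage 3: libraries


def _default_effect_map(truth: GroundTruth, rng: np.random.Generator):
    """Mixed design: strong responders, unchanged, and exclusives.

    Known: 6 responders, 2 high-expression unchanged, 2 low-expression
    unchanged.  New members: 3 responders, 2 low unchanged.  Candidates:
    two XZ29-exclusive, one GP-exclusive, one responder, one low unchanged
    (mirroring the genotype-exclusive candidates the design anticipates).
    """
    effects: Dict[str, Dict[str, float]] = {}
    baselines: Dict[str, float] = {}
    # baseline means are expressed at a reference depth of 1e6 and scaled,
    # so expected CPM (and hence the responsiveness rules) are depth-free
    scale = truth.config.library_depth / 1e6
    by_class = {
        "known": [l for l in truth.loci if l.class_label == "known"],
        "new_member": [l for l in truth.loci if l.class_label == "new_member"],
        "candidate": [l for l in truth.loci if l.class_label == "candidate"],
    }
    strong = [4.0, 0.25]

    def assign(loc, role):
        if role == "responder":
            f = {g: float(rng.choice(strong + [1.0])) for g in GENOTYPES}
            if all(x == 1.0 for x in f.values()):
                f["XZ29"] = 4.0
            effects[loc.name] = f
            baselines[loc.name] = float(rng.uniform(500, 5000)) * scale
        elif role == "high_unchanged":
            effects[loc.name] = {g: 1.0 for g in GENOTYPES}
            baselines[loc.name] = float(rng.uniform(500, 3000)) * scale
        elif role == "low_unchanged":
            effects[loc.name] = {g: 1.0 for g in GENOTYPES}
            baselines[loc.name] = float(rng.uniform(8, 15)) * scale
        elif role == "excl_xz29":
            effects[loc.name] = {"GP": 0.0, "XZ29": float(rng.choice(strong))}
            baselines[loc.name] = float(rng.uniform(500, 3000)) * scale
        elif role == "excl_gp":
            effects[loc.name] = {"GP": float(rng.choice(strong)), "XZ29": 0.0}
            baselines[loc.name] = float(rng.uniform(500, 3000)) * scale

    roles = {
        "known": ["responder"] * 6 + ["high_unchanged"] * 2 + ["low_unchanged"] * 2,
        "new_member": ["responder"] * 3 + ["low_unchanged"] * 2,
        "candidate": ["excl_xz29", "excl_xz29", "excl_gp", "responder", "low_unchanged"],
    }
    for cl, locs in by_class.items():
        plan = roles[cl]
        for loc, role in zip(locs, (plan * ((len(locs) // len(plan)) + 1))[: len(locs)]):
            assign(loc, role)
    return effects, baselines


def _expected_mean(base: float, factor: float, treatment: str) -> float:
    if factor == 0:
        return 0.0
    return base * factor if treatment == "Al" else base


def _make_read(insert: str, adapter: str, read_length: int) -> str:
    read = insert + adapter
    if len(read) < read_length:
        read = read + "A" * (read_length - len(read))
    return read[:read_length]


def simulate_libraries(
    truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
    refs: Optional[dict] = None,
):
    """Draw raw reads for the eight libraries.

    Returns (reads_per_library, expected) where reads_per_library maps
    library id -> list of (raw_read, count) and ``expected`` is a DataFrame
    of per-species expected mean counts (one row per distinct read species,
    with its truth bin), whose per-library column sums equal the configured
    depth up to rounding.
    """
    cfg = config or truth.config
    cfg.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    refs = refs or make_references(truth, np.random.default_rng(np.random.SeedSequence([cfg.seed, 1])))

    if truth.effect_map and truth.baselines:
        effects, baselines = truth.effect_map, truth.baselines
    elif cfg.effect_map is not None:
        effects = cfg.effect_map
        baselines = truth.baselines or {
            l.name: float(rng.uniform(500, 5000)) for l in truth.loci
        }
    else:
        effects, baselines = _default_effect_map(truth, rng)
    truth.effect_map, truth.baselines = effects, baselines

    depth = cfg.library_depth
    budgets = {k: cfg.fractions[k] * depth for k in cfg.fractions}
    valid_budget = depth - sum(budgets.values())

    # --- enumerate read species: (key, raw_read, bin, per-library mean fn)
    species: List[Tuple[str, str, str, Dict[str, float]]] = []
    libs = cfg.libraries

    def lib_means(mean_ctrl_fn) -> Dict[str, float]:
        return {library_id(g, t, r): mean_ctrl_fn(g, t) for g, t, r in cfg.design}

    planted_sum = {lib: 0.0 for lib in libs}
    for loc in truth.loci:
        base = baselines[loc.name]
        means = lib_means(
            lambda g, t, b=base, n=loc.name: _expected_mean(b, effects[n][g], t)
        )
        for lib in libs:
            planted_sum[lib] += means[lib]
        species.append((loc.name, _make_read(loc.mature_seq, cfg.adapter, cfg.read_length), "valid", means))

    # filler valid tags: genome windows keeping per-library valid totals equal
    filler_need = {lib: valid_budget - planted_sum[lib] for lib in libs}
    if min(filler_need.values()) < 0:
        raise ValueError("planted expression exceeds the valid read budget")
    n_fill = max(cfg.n_filler_tags, 1)
    glen = len(truth.genome)
    forbidden = [(l.start, l.end) for l in truth.loci]
    fill_seqs = []
    while len(fill_seqs) < n_fill:
        p = int(rng.integers(0, glen - 30))
        if any(s - 30 <= p <= e for s, e in forbidden):
            continue
        frag = truth.genome[p : p + int(rng.integers(20, 25))]
        if not is_junk(frag):
            fill_seqs.append(frag)
    for k, frag in enumerate(fill_seqs, start=1):
        means = {lib: filler_need[lib] / n_fill for lib in libs}
        species.append((f"filler{k:02d}", _make_read(frag, cfg.adapter, cfg.read_length), "valid", means))

    # contaminant species from the reference sets
    def window_species(klass, bin_name):
        entries = refs.get(klass, [])
        n = cfg.n_species[klass]
        budget = budgets[klass]
        out = []
        for k in range(n):
            name, seq = entries[int(rng.integers(0, len(entries)))]
            if len(seq) < 26:
                continue
            p = int(rng.integers(0, len(seq) - 25))
            frag = seq[p : p + int(rng.integers(18, 26))]
            if is_junk(frag):
                continue
            means = {lib: budget / n for lib in libs}
            out.append((f"{klass}_frag{k:02d}", _make_read(frag, cfg.adapter, cfg.read_length), bin_name, means))
        # put skipped budget back on the first species so totals stay exact
        short = n - len(out)
        if out and short:
            name0, read0, b0, m0 = out[0]
            out[0] = (name0, read0, b0, {lib: m0[lib] + short * budget / n for lib in libs})
        return out

    for klass in ("rfam", "mrna", "repeat"):
        species.extend(window_species(klass, klass))

    # junk, short fragments, adapter-less reads
    junk_kinds = []
    bases = "ACGT"
    for k in range(cfg.n_species["junk"]):
        if k % 2 == 0:
            junk_kinds.append(bases[(k // 2) % 4] * int(rng.integers(18, 26)))
        else:
            d = bases[k % 4] + bases[(k + 1) % 4]
            junk_kinds.append((d * 13)[: int(rng.integers(18, 26))])
    for k, j in enumerate(junk_kinds, 1):
        means = {lib: budgets["junk"] / len(junk_kinds) for lib in libs}
        species.append((f"junk{k:02d}", _make_read(j, cfg.adapter, cfg.read_length), "junk", means))

    n_short = cfg.n_species["short"]
    for k in range(1, n_short + 1):
        frag = _random_seq(rng, int(rng.integers(10, 18)))
        means = {lib: budgets["short"] / n_short for lib in libs}
        species.append((f"short{k:02d}", _make_read(frag, cfg.adapter, cfg.read_length), "length_fail", means))

    n_na = cfg.n_species["adapter_fail"]
    for k in range(1, n_na + 1):
        read = _random_seq(rng, cfg.read_length)
        means = {lib: budgets["adapter_fail"] / n_na for lib in libs}
        species.append((f"noadapter{k:02d}", read, "adapter_fail", means))

    # --- draw counts
    reads_per_library: Dict[str, List[Tuple[str, int]]] = {lib: [] for lib in libs}
    rows = []
    d = cfg.dispersion
    for name, read, bin_name, means in species:
        row = {"species": name, "read": read, "bin": bin_name}
        for lib in libs:
            m = means[lib]
            row[lib] = m
            if m <= 0:
                continue
            if d == 0:
                count = int(round(m))
            else:
                r = 1.0 / d
                count = int(rng.negative_binomial(r, r / (r + m)))
            if count > 0:
                if cfg.sequencing_error_rate > 0:
                    read_out = _mutate(read, cfg.sequencing_error_rate, rng)
                else:
                    read_out = read
                reads_per_library[lib].append((read_out, count))
        rows.append(row)
    expected = pd.DataFrame(rows).set_index("species")
    return reads_per_library, expected


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    s = list(read)
    for i in range(len(s)):
        if rng.random() < rate:
            s[i] = str(rng.choice([c for c in "ACGT" if c != s[i]]))
    return "".join(s)


# ---------------------------------------------------------------------------
# Stage 4: targets and degradome


def make_transcriptome(truth: GroundTruth, rng: Optional[np.random.Generator] = None):
    """Target transcripts with planted complementary sites.

    Each selected miRNA gets one transcript carrying the reverse complement
    of its mature sequence (0-1 mismatches outside the seed); the cleavage
    position (opposite miRNA position 10) is recorded in the truth.
    """
    cfg = truth.config
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    chosen = truth.loci[: cfg.n_target_transcripts]
    transcripts = []
    pairs = []
    for k, loc in enumerate(chosen, start=1):
        tid = f"TRANS{k:03d}"
        tl = cfg.transcript_length
        seq = list(_random_seq(rng, tl, gc=0.5))
        site = revcomp(loc.mature_seq)
        L = len(site)
        n_mm = int(rng.integers(0, 2))
        mism = 0
        if n_mm:
            # mismatch outside the seed-facing part: miRNA positions 14..L
            mir_pos = int(rng.integers(14, L + 1))
            site_idx = L - mir_pos  # 0-based within site
            orig = site[site_idx]
            site = site[:site_idx] + str(rng.choice([c for c in "ACGT" if c != orig])) + site[site_idx + 1 :]
            mism = 1
        a = int(rng.integers(50, tl - L - 50))
        seq[a : a + L] = list(site)
        seq_s = "".join(seq)
        cleavage = a + 1 + L - 10  # 1-based transcript pos opposite miRNA pos 10
        transcripts.append((tid, seq_s))
        pairs.append(TargetPair(loc.name, tid, a + 1, a + L, cleavage, mism))
    truth.transcripts = transcripts
    truth.target_pairs = pairs
    return transcripts, pairs


def simulate_degradome(
    truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Degradome reads: 5' ends at true cleavage sites plus uniform background.

    Returns (reads, cleavage_table) where reads is a list of (name, seq) and
    cleavage_table a DataFrame of the true cleavage positions.
    """
    cfg = config or truth.config
    rng = rng or np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    if not truth.transcripts:
        make_transcriptome(truth, np.random.default_rng(np.random.SeedSequence([cfg.seed, 3])))
    sig = cfg.degradome_signal_fraction
    if not 0 <= sig <= 1:
        raise ValueError("degradome_signal_fraction must be in [0, 1]")
    rl = cfg.degradome_read_length
    total = cfg.degradome_reads_per_transcript
    reads = []
    rows = []
    tmap = dict(truth.transcripts)
    for pair in truth.target_pairs:
        seq = tmap[pair.transcript_id]
        if not 1 <= pair.cleavage_pos <= len(seq):
            raise ValueError(f"cleavage position {pair.cleavage_pos} outside {pair.transcript_id}")
        n_sig = int(round(sig * total))
        n_bg = total - n_sig
        for k in range(n_sig):
            frag = seq[pair.cleavage_pos - 1 : pair.cleavage_pos - 1 + rl]
            reads.append((f"{pair.transcript_id}_sig{k}", frag))
        for k in range(n_bg):
            # background covers positions other than the cleavage site
            p = int(rng.integers(0, max(1, len(seq) - rl)))
            while p == pair.cleavage_pos - 1:
                p = int(rng.integers(0, max(1, len(seq) - rl)))
            reads.append((f"{pair.transcript_id}_bg{k}", seq[p : p + rl]))
        rows.append(
            {
                "mirna": pair.mirna,
                "transcript": pair.transcript_id,
                "cleavage_pos": pair.cleavage_pos,
                "signal_reads": n_sig,
            }
        )
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Convenience driver


def simulate_experiment(config: SimulationConfig):
    """Run all generator stages; returns (truth, refs, reads, expected)."""
    genome, truth = make_genome(config)
    refs = make_references(truth)
    reads, expected = simulate_libraries(truth, config, refs=refs)
    make_transcriptome(truth)
    return truth, refs, reads, expected
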