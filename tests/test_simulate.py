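"""Synthetic-data generator: determinism, planting, budgets, noise model."""

import numpy as np
import pandas as pd
import pytest

from almirna.fold import check_criteria
from almirna.io import revcomp
from almirna.simulate import (
    SimulationConfig,
    default_design,
    make_genome,
    make_references,
    simulate_degradome,
    simulate_experiment,
    simulate_libraries,
    make_transcriptome,
)


def tiny_config(**kw):
    base = dict(
        seed=11,
        genome_length=40_000,
        n_known=3,
        n_new_member=2,
        n_candidate=2,
        library_depth=50_000,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_design_must_be_complete(self):
        cfg = tiny_config(design=default_design()[:6])
        with pytest.raises(ValueError, match="design"):
            cfg.validate()

    def test_negative_effect_rejected(self):
        cfg = tiny_config(effect_map={"x": {"GP": -1.0, "XZ29": 1.0}})
        with pytest.raises(ValueError, match="effect factor"):
            cfg.validate()

    def test_degenerate_adapter_rejected(self):
        with pytest.raises(ValueError, match="adapter"):
            tiny_config(adapter="AAAA").validate()


class TestMakeGenome:
    def test_no_planting_gives_empty_loci(self):
        genome, truth = make_genome(tiny_config(n_known=0, n_new_member=0, n_candidate=0))
        assert truth.loci == []
        assert len(genome) == 40_000

    def test_determinism_by_seed(self):
        g1, t1 = make_genome(tiny_config())
        g2, t2 = make_genome(tiny_config())
        assert g1 == g2
        assert [(l.name, l.start, l.end, l.strand) for l in t1.loci] == [
            (l.name, l.start, l.end, l.strand) for l in t2.loci
        ]

    def test_loci_relocatable_by_substring_search(self):
        genome, truth = make_genome(tiny_config(n_known=5, n_new_member=0, n_candidate=0))
        assert len(truth.loci) == 5
        for loc in truth.loci:
            embedded = genome[loc.start - 1 : loc.end]
            oriented = loc.precursor_seq if loc.strand == "+" else revcomp(loc.precursor_seq)
            assert embedded == oriented
            assert genome.count(oriented) == 1

    def test_loci_separated_for_flank_extraction(self):
        genome, truth = make_genome(tiny_config())
        spans = sorted((l.start, l.end) for l in truth.loci)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= 240

    def test_genome_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            make_genome(tiny_config(genome_length=2_000))

    def test_planted_hairpins_pass_all_criteria(self):
        _, truth = make_genome(tiny_config())
        for loc in truth.loci:
            rep = check_criteria(loc.structure, loc.mature_span)
            assert rep.passed, f"{loc.name} fails criteria"
            assert 20 <= len(loc.mature_seq) <= 24
            assert loc.metrics.mfei > 0.85


class TestMakeReferences:
    def test_class_membership_rules(self):
        _, truth = make_genome(tiny_config(n_known=1, n_new_member=1, n_candidate=1))
        refs = make_references(truth)
        known = truth.loci[0]
        newm = truth.loci[1]
        cand = truth.loci[2]
        mature_seqs = [s for _, s in refs["mature"]]
        precursor_seqs = [s for _, s in refs["precursor"]]
        assert len(refs["mature"]) == 1
        # known mature present up to 2 planted mismatches
        mm = min(sum(a != b for a, b in zip(known.mature_seq, s)) for s in mature_seqs)
        assert mm <= 2
        assert any(newm.precursor_seq == s for s in precursor_seqs)
        assert all(cand.mature_seq not in s for s in mature_seqs + precursor_seqs)

    def test_empty_truth_still_emits_contaminants(self):
        _, truth = make_genome(tiny_config(n_known=0, n_new_member=0, n_candidate=0))
        refs = make_references(truth)
        assert refs["mature"] == [] and refs["precursor"] == []
        assert len(refs["rfam"]) > 0 and len(refs["mrna"]) > 0


class TestSimulateLibraries:
    def test_expected_totals_equal_depth(self):
        cfg = tiny_config()
        _, truth = make_genome(cfg)
        _, expected = simulate_libraries(truth, cfg)
        for lib in cfg.libraries:
            assert expected[lib].sum() == pytest.approx(cfg.library_depth)

    def test_effect_factor_semantics(self):
        cfg = tiny_config()
        _, truth = make_genome(cfg)
        _, expected = simulate_libraries(truth, cfg)
        for loc in truth.loci:
            row = expected.loc[loc.name]
            for g in ("GP", "XZ29"):
                f = truth.effect_map[loc.name][g]
                ctrl = row[f"{g}_control_1"]
                al = row[f"{g}_Al_1"]
                if f == 0:
                    assert ctrl == 0 and al == 0
                else:
                    assert al == pytest.approx(ctrl * f)

    def test_determinism(self):
        cfg = tiny_config()
        _, t1 = make_genome(cfg)
        r1, e1 = simulate_libraries(t1, cfg)
        _, t2 = make_genome(cfg)
        r2, e2 = simulate_libraries(t2, cfg)
        assert r1 == r2
        assert e1.equals(e2)

    def test_zero_dispersion_counts_are_exact_means(self):
        cfg = tiny_config(dispersion=0.0)
        _, truth = make_genome(cfg)
        reads, expected = simulate_libraries(truth, cfg)
        lib = "GP_control_1"
        realized = dict(reads[lib])
        for loc in truth.loci:
            m = expected.loc[loc.name, lib]
            read = expected.loc[loc.name, "read"]
            assert realized.get(read, 0) == round(m)

    def test_low_dispersion_counts_converge_to_means(self):
        # Monte-Carlo over 20 seeds at depth 1e6: per-tag mean relative
        # error below 5% in the near-deterministic dispersion limit
        cfg = tiny_config(library_depth=1_000_000, dispersion=1e-3)
        _, truth = make_genome(cfg)
        lib = "XZ29_Al_2"
        sums = {}
        expected = None
        for seed in range(20):
            rng = np.random.default_rng(seed + 100)
            reads, expected = simulate_libraries(truth, cfg, rng=rng)
            realized = dict(reads[lib])
            for loc in truth.loci:
                read = expected.loc[loc.name, "read"]
                sums[loc.name] = sums.get(loc.name, 0) + realized.get(read, 0)
        for loc in truth.loci:
            m = expected.loc[loc.name, lib]
            if m < 50:  # relative error is not meaningful for tiny means
                continue
            assert abs(sums[loc.name] / 20 - m) / m < 0.05


class TestDegradome:
    def test_signal_one_all_reads_at_cleavage_sites(self):
        cfg = tiny_config(degradome_signal_fraction=1.0)
        _, truth = make_genome(cfg)
        make_transcriptome(truth)
        reads, table = simulate_degradome(truth, cfg)
        tmap = dict(truth.transcripts)
        starts = {
            p.transcript_id: tmap[p.transcript_id][p.cleavage_pos - 1 : p.cleavage_pos + 19]
            for p in truth.target_pairs
        }
        for name, seq in reads:
            tid = name.split("_")[0]
            assert seq == starts[tid]

    def test_cleavage_is_modal_five_prime_end(self):
        # signal 0.5 / background 0.5 over a 500-nt transcript: the cleavage
        # site is the modal 5' end with high probability at 1000 reads
        cfg = tiny_config()
        _, truth = make_genome(cfg)
        make_transcriptome(truth)
        hits = 0
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            reads, _ = simulate_degradome(truth, cfg, rng=rng)
            tmap = dict(truth.transcripts)
            for pair in truth.target_pairs:
                seq = tmap[pair.transcript_id]
                counts = {}
                for name, r in reads:
                    if name.startswith(pair.transcript_id + "_"):
                        pos = seq.find(r)
                        counts[pos] = counts.get(pos, 0) + 1
                modal = max(counts, key=counts.get)
                total += 1
                hits += modal == pair.cleavage_pos - 1
        assert hits == total

    def test_transcripts_carry_target_sites(self):
        cfg = tiny_config()
        _, truth = make_genome(cfg)
        transcripts, pairs = make_transcriptome(truth)
        tmap = dict(transcripts)
        for p in pairs:
            site = tmap[p.transcript_id][p.site_start - 1 : p.site_end]
            mature = truth.locus(p.mirna).mature_seq
            mm = sum(a != b for a, b in zip(site, revcomp(mature)))
            assert mm == p.mismatches <= 1


def test_experiment_runs_end_to_end():
    truth, refs, reads, expected = simulate_experiment(tiny_config())
    assert len(reads) == 8
    assert len(truth.loci) == 7
    assert truth.responsive_truth()
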