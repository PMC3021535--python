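"""Generator contracts: determinism, probe arithmetic, planted-truth shape."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hsfchip import io as hio
from hsfchip import segments as seg
from hsfchip import synthetic
from hsfchip.synthetic import (
    GroundTruth,
    PlantedSegment,
    SyntheticConfig,
    generate_genome,
    generate_probes,
)

from conftest import NOISE_FREE_CONFIG, SMALL_CONFIG


class TestConfigValidation:
    def test_category_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="category_mix"):
            SyntheticConfig(category_mix={"promoter": 0.5, "intron": 0.6})

    def test_fractions_in_unit_interval(self):
        with pytest.raises(ValueError, match="rt_retained_fraction"):
            SyntheticConfig(rt_retained_fraction=1.2)

    def test_probe_spacing_positive(self):
        with pytest.raises(ValueError, match="probe_spacing"):
            SyntheticConfig(probe_spacing=0)

    def test_overlapping_probes_flagged(self):
        with pytest.warns(UserWarning, match="overlap"):
            SyntheticConfig(probe_length=300, probe_spacing=233)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump({"n_segments": 12, "seed": 9}))
        cfg = SyntheticConfig.from_yaml(path)
        assert cfg.n_segments == 12 and cfg.seed == 9


class TestGenerateGenome:
    def test_deterministic_outputs(self, tmp_path):
        cfg = dataclasses.replace(SMALL_CONFIG, n_segments=10, seed=21)
        s1 = synthetic.simulate_study(cfg)
        s2 = synthetic.simulate_study(dataclasses.replace(cfg))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        s1.write(d1)
        s2.write(d2)
        for name in ("genome.fa", "annotation.gff3", "chip_hs.tsv", "expression.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_zero_genes_valid_empty_annotation(self, tmp_path):
        cfg = SyntheticConfig(n_genes=0, n_chromosomes=1, genome_length=50_000)
        genome, annotation = generate_genome(cfg)
        assert len(annotation) == 0
        hio.write_gff3(annotation, tmp_path / "empty.gff3")
        back = hio.read_gff3(tmp_path / "empty.gff3")
        assert len(back) == 0
        assert back.chrom_lengths == {"chr1": 50_000}

    def test_too_small_genome_names_constraint(self):
        cfg = SyntheticConfig(genome_length=50_000, n_chromosomes=1, n_genes=50)
        with pytest.raises(ValueError, match="genome too small"):
            generate_genome(cfg)

    def test_transcript_coverage_near_target(self):
        """Union of transcribed spans matches the mean of the length model."""
        cfg = SyntheticConfig(
            genome_length=2_000_000, n_chromosomes=1, n_genes=100, seed=2
        )
        _, annotation = generate_genome(cfg)
        covered = 0
        for gene in annotation.genes:
            start, end = gene.span
            covered += end - start
        coverage = covered / 2_000_000
        target = 100 * np.mean(cfg.gene_length_range) / 2_000_000
        # 100 iid uniform lengths: 3 sigma of the mean is ~3.5% relative
        assert coverage == pytest.approx(target, rel=0.05)

    def test_isoform_structure_valid(self, small_study):
        for gene in small_study.annotation.genes:
            for iso in gene.isoforms:
                assert iso.start < iso.end
                assert iso.exons[0][0] == iso.start
                assert iso.exons[-1][1] == iso.end
                for (s1, e1), (s2, e2) in zip(iso.exons, iso.exons[1:]):
                    assert e1 <= s2


class TestGenerateProbes:
    def test_probe_count_arithmetic_no_mask(self):
        cfg = SyntheticConfig(masked_gap_fraction=0.0, super_gap_length=0)
        probes, masks = generate_probes({"chr1": 10_000}, cfg)
        assert len(masks) == 0
        assert len(probes) == 10_000 // 233 + 1
        assert list(probes["start"][:3]) == [0, 233, 466]

    def test_no_probe_intersects_a_mask(self, small_study):
        probes, masks = small_study.probes, small_study.masks
        for _, m in masks.iterrows():
            inside = probes[
                (probes["chrom"] == m["chrom"])
                & (probes["start"] < m["end"])
                & (m["start"] < probes["end"])
            ]
            assert len(inside) == 0

    def test_super_gap_planted(self, small_study):
        sizes = small_study.masks["end"] - small_study.masks["start"]
        assert sizes.max() >= 10 * small_study.config.probe_spacing


class TestGroundTruth:
    def test_hse_offsets_inside_window(self, small_study):
        truth = small_study.truth
        lo, hi = small_study.config.hse_window
        hse = [m for m in truth.planted_motifs if m.motif_id == synthetic.HSE_MOTIF_ID]
        assert hse
        for motif in hse:
            assert lo <= motif.offset <= hi

    def test_peak_inside_span_enforced(self):
        with pytest.raises(ValueError, match="peak"):
            PlantedSegment("chr1", 100, 200, 300, "intron", 20.0, True)

    def test_invalid_hse_offset_rejected(self):
        seg_ok = PlantedSegment("chr1", 0, 1_400, 700, "intron", 20.0, True)
        motif = synthetic.PlantedMotif("chr1", 2_000, "+", synthetic.HSE_MOTIF_ID, 999, 0)
        with pytest.raises(ValueError, match="outside"):
            GroundTruth([seg_ok], [motif])

    def test_planted_sequence_contains_consensus_cores(self, small_study):
        from hsfchip.motifs import reverse_complement

        genome = small_study.genome
        for motif in small_study.truth.planted_motifs[:25]:
            if motif.motif_id != synthetic.HSE_MOTIF_ID:
                continue
            window = genome[motif.chrom][motif.position : motif.position + 15]
            if motif.strand == "-":
                window = reverse_complement(window)
            assert window[1:4] == "GAA" and window[6:9] == "TTC" and window[11:14] == "GAA"


class TestChipSignal:
    def test_noise_free_peak_probe_has_max_fold(self, noise_free_study):
        truth = noise_free_study.truth
        hs = noise_free_study.chip["hs"]
        for segment in truth.planted_segments[:20]:
            members = hs[
                (hs["chrom"] == segment.chrom)
                & (hs["start"] >= segment.start)
                & (hs["end"] <= segment.end)
            ]
            best = members.loc[members["fold"].idxmax()]
            assert abs((best["start"] + best["end"]) // 2 - segment.peak) <= 30

    def test_rt_only_on_retained_segments(self, noise_free_study):
        truth = noise_free_study.truth
        rt = noise_free_study.chip["rt"]
        for segment in truth.planted_segments:
            members = rt[
                (rt["chrom"] == segment.chrom)
                & (rt["start"] >= segment.start)
                & (rt["end"] <= segment.end)
            ]
            enriched = (members["fold"] > 2.0).any()
            assert enriched == segment.has_rt_signal

    def test_mock_background_has_no_called_segments(self, noise_free_study):
        called = seg.call_segments(noise_free_study.chip["mock"])
        planted_mock = {(s.chrom, s.start) for s in noise_free_study.truth.mock_segments}
        assert len(called) == len(planted_mock)

    def test_pxbar_monotone_in_fold_noise_free(self, noise_free_study):
        hs = noise_free_study.chip["hs"].sort_values("fold")
        pxbar = hs["pxbar"].to_numpy()
        fold = hs["fold"].to_numpy()
        order = np.argsort(fold)
        assert np.all(np.diff(pxbar[order]) <= 1e-300)


class TestExpression:
    def test_zero_de_fraction_no_calls(self):
        from hsfchip import expression as expr

        cfg = dataclasses.replace(
            SMALL_CONFIG,
            de_fraction_per_system=0.0,
            induced_bound_fraction=0.0,
            n_segments=10,
            seed=8,
        )
        study = synthetic.simulate_study(cfg)
        calls = expr.differential_calls(study.expression)
        assert (calls["status"] == "unchanged").all()

    def test_noise_free_recovery_exact(self, noise_free_study):
        from hsfchip import expression as expr

        calls = expr.differential_calls(noise_free_study.expression)
        for system, planted in noise_free_study.truth.responsive_genes.items():
            recovered = expr.calls_to_sets(calls, system)["changed"]
            assert recovered == set(planted)

    def test_overlap_fraction_near_configured(self, small_study):
        truth = small_study.truth
        a = set(truth.responsive_genes["cells"])
        b = set(truth.responsive_genes["larvae"])
        overlap = len(a & b) / len(a | b)
        assert overlap == pytest.approx(
            small_study.config.de_overlap_fraction, abs=0.04
        )

    def test_mutant_response_mostly_suppressed(self, small_study):
        truth = small_study.truth
        expected = min(
            small_study.config.mutant_responsive_count,
            len(truth.responsive_genes["larvae"]),
        )
        assert len(truth.responsive_genes["mutant"]) == expected
        assert set(truth.responsive_genes["mutant"]) <= set(
            truth.responsive_genes["larvae"]
        )


class TestCytology:
    def test_bands_partition_each_chromosome(self, small_study):
        for chrom, group in small_study.band_map.groupby("chrom"):
            group = group.sort_values("start")
            assert group["start"].iloc[0] == 0
            assert group["end"].iloc[-1] == small_study.config.genome_length
            assert (group["start"].iloc[1:].to_numpy() == group["end"].iloc[:-1].to_numpy()).all()

    def test_full_rate_zero_jitter_covers_all_segment_bands(self):
        from hsfchip import annotation as ann

        cfg = dataclasses.replace(
            SMALL_CONFIG,
            locus_rate=1.0,
            locus_jitter=0,
            background_locus_rate=0.0,
            n_segments=15,
            seed=13,
        )
        study = synthetic.simulate_study(cfg)
        loci = set(study.polytene_loci["band"].astype(str))
        for segment in study.truth.planted_segments:
            band = ann.map_to_band(study.band_map, segment.chrom, segment.peak)
            assert band in loci

    def test_jitter_one_keeps_loci_within_one_band(self):
        from hsfchip import annotation as ann

        cfg = dataclasses.replace(
            SMALL_CONFIG,
            locus_rate=1.0,
            locus_jitter=1,
            locus_jitter_prob=1.0,
            background_locus_rate=0.0,
            n_segments=15,
            seed=14,
        )
        study = synthetic.simulate_study(cfg)
        index_of = {
            str(r["band"]): (r["chrom"], int(r["index"]))
            for _, r in study.band_map.iterrows()
        }
        site_indices = {}
        for segment in study.truth.planted_segments:
            band = ann.map_to_band(study.band_map, segment.chrom, segment.peak)
            chrom, idx = index_of[band]
            site_indices.setdefault(chrom, set()).add(idx)
        for band in study.polytene_loci["band"].astype(str):
            chrom, idx = index_of[band]
            assert any(abs(idx - s) <= 1 for s in site_indices.get(chrom, set()))


class TestRoundTrip:
    def test_written_files_reload_losslessly(self, small_study, tmp_path):
        out = small_study.write(tmp_path / "study")
        genome = hio.read_fasta(out / "genome.fa")
        assert genome == small_study.genome
        annotation = hio.read_gff3(out / "annotation.gff3")
        assert len(annotation) == len(small_study.annotation)
        chip = hio.read_tsv(out / "chip_hs.tsv")
        pd.testing.assert_frame_equal(chip, small_study.chip["hs"])
        manifest = hio.read_json(out / "manifest.json")
        assert manifest["seed"] == small_study.config.seed
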