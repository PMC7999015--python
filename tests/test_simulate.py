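"""Synthetic reciprocal-cross generator: planted truth and determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from fvimprint import (
    GeneSpec,
    SimulationConfig,
    make_parental_haplotypes,
    sample_clone_reads,
    simulate_qpcr,
)
from fvimprint.simulate import parental_clone_reads


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestGeneSpec:
    def test_more_snps_than_sites_rejected(self):
        with pytest.raises(ValueError, match="exceeds CDS length"):
            GeneSpec("g", 10, 11)

    def test_state_defaults_follow_ploidy_expectations(self):
        biallelic = GeneSpec("g", 100, 1, "BIALLELIC")
        assert biallelic.maternal_fraction("endosperm") == pytest.approx(2 / 3)
        assert biallelic.maternal_fraction("embryo") == pytest.approx(1 / 2)
        meg = GeneSpec("g", 100, 1, "MEG")
        assert meg.maternal_fraction("endosperm") == 1.0

    def test_fraction_override_wins(self):
        gene = GeneSpec("g", 100, 1, "MEG", maternal_fraction_endosperm=0.9)
        assert gene.maternal_fraction("endosperm") == 0.9


class TestHaplotypes:
    def test_zero_snps_gives_identical_parents(self):
        config = SimulationConfig(seed=1, genes=(GeneSpec("g", 80, 0),))
        haps, manifest = make_parental_haplotypes(config)
        a, b = (haps["g"][p] for p in config.parents)
        assert a == b
        assert manifest.empty

    @pytest.mark.parametrize("n_snps", [1, 7, 19])
    def test_planted_count_equals_hamming_distance(self, n_snps):
        config = SimulationConfig(seed=3, genes=(GeneSpec("g", 200, n_snps),))
        haps, manifest = make_parental_haplotypes(config)
        a, b = (haps["g"][p] for p in config.parents)
        assert hamming(a, b) == n_snps
        assert len(manifest) == n_snps
        # manifest records the truth at 1-based positions
        for _, row in manifest.iterrows():
            pos = row["position"] - 1
            assert a[pos] == row[config.parents[0]]
            assert b[pos] == row[config.parents[1]]
            assert a[pos] != b[pos]

    def test_same_seed_reproduces_identical_sequences(self):
        config = SimulationConfig(seed=9, genes=(GeneSpec("g", 150, 5),))
        haps1, man1 = make_parental_haplotypes(config)
        haps2, man2 = make_parental_haplotypes(config)
        assert haps1 == haps2
        pd.testing.assert_frame_equal(man1, man2)


class TestCloneSampling:
    def setup_method(self):
        self.gene = GeneSpec("g", 60, 2)
        self.config = SimulationConfig(seed=21, genes=(self.gene,))
        self.haps, _ = make_parental_haplotypes(self.config)

    def test_unknown_tissue_and_direction_rejected(self):
        d1 = self.config.cross_directions[0]
        with pytest.raises(ValueError, match="tissue"):
            sample_clone_reads(self.gene, "leaf", d1, self.config, self.haps)
        with pytest.raises(ValueError, match="direction"):
            sample_clone_reads(
                self.gene, "embryo", ("10-41", "unknown"), self.config, self.haps
            )

    def test_reads_are_copies_of_parental_haplotypes(self):
        d1 = self.config.cross_directions[0]
        sample = sample_clone_reads(self.gene, "endosperm", d1, self.config, self.haps)
        assert len(sample) == self.config.clones_per_sample
        for read, origin in zip(sample.reads, sample.origins):
            parent = d1[0] if origin == "maternal" else d1[1]
            assert read == self.haps["g"][parent]

    def test_meg_gene_yields_only_maternal_clones(self):
        gene = GeneSpec("g", 60, 2, "MEG", maternal_fraction_embryo=1.0)
        for tissue in ("endosperm", "embryo"):
            sample = sample_clone_reads(
                gene, tissue, self.config.cross_directions[0], self.config, self.haps
            )
            assert set(sample.origins) == {"maternal"}

    @pytest.mark.parametrize(
        "tissue,fraction", [("endosperm", 2 / 3), ("embryo", 1 / 2)]
    )
    def test_origin_proportion_converges_to_ploidy_fraction(self, tissue, fraction):
        """Binomial law: at 10,000 clones the maternal-origin proportion
        sits within 3 binomial SE of the configured fraction."""
        sample = sample_clone_reads(
            self.gene, tissue, self.config.cross_directions[0], self.config,
            self.haps, n_clones=10_000,
        )
        prop = sample.origins.count("maternal") / 10_000
        se = math.sqrt(fraction * (1 - fraction) / 10_000)
        assert abs(prop - fraction) <= 3 * se

    def test_same_seed_regenerates_identical_sample(self):
        d2 = self.config.cross_directions[1]
        s1 = sample_clone_reads(self.gene, "embryo", d2, self.config, self.haps)
        s2 = sample_clone_reads(self.gene, "embryo", d2, self.config, self.haps)
        assert s1.reads == s2.reads and s1.origins == s2.origins

    def test_swapping_parent_labels_swaps_origin_labels_exactly(self):
        """Regenerating with the parents listed in the opposite order and
        the same seed yields the same clones with maternal/paternal
        ground-truth labels exchanged."""
        swapped = SimulationConfig(
            seed=self.config.seed, genes=self.config.genes,
            parents=(self.config.parents[1], self.config.parents[0]),
        )
        orig = sample_clone_reads(
            self.gene, "endosperm", self.config.cross_directions[0],
            self.config, self.haps,
        )
        swap = sample_clone_reads(
            self.gene, "endosperm", swapped.cross_directions[0], swapped, self.haps
        )
        # same Bernoulli stream: origin labels identical, but the maternal
        # parent differs, so each clone's underlying ecotype is swapped
        assert orig.origins == swap.origins
        for r_orig, r_swap, origin in zip(orig.reads, swap.reads, orig.origins):
            assert r_orig == self.haps["g"][
                self.config.parents[0] if origin == "maternal" else self.config.parents[1]
            ]
            assert r_swap == self.haps["g"][
                swapped.parents[0] if origin == "maternal" else swapped.parents[1]
            ]

    def test_read_errors_applied_at_configured_rate(self):
        config = SimulationConfig(
            seed=5, genes=(self.gene,), per_base_read_error=0.1
        )
        sample = sample_clone_reads(
            self.gene, "embryo", config.cross_directions[0], config, self.haps,
            n_clones=200,
        )
        mismatches = sum(
            hamming(read, self.haps["g"][d[0] if o == "maternal" else d[1]])
            for read, o, d in zip(
                sample.reads, sample.origins,
                [config.cross_directions[0]] * len(sample.reads),
            )
        )
        total = 200 * self.gene.cds_length
        se = math.sqrt(0.1 * 0.9 / total)
        assert abs(mismatches / total - 0.1) <= 4 * se


class TestSimulateQpcr:
    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            simulate_qpcr("g", {"leaf": 1.0, "root": 0.0}, "leaf", seed=1)

    def test_layout_is_three_by_four_per_tissue(self):
        ct = simulate_qpcr("g", {"leaf": 1.0, "root": 2.0}, "leaf", seed=1)
        layout = ct.groupby(["tissue", "bio_rep"])["tech_rep"].count()
        assert (layout == 4).all()
        assert ct["bio_rep"].nunique() == 3

    def test_zero_noise_encodes_exact_fold_change(self):
        ct = simulate_qpcr("g", {"leaf": 1.0, "endosperm": 8.0}, "leaf", seed=1)
        dct = ct.groupby("tissue").apply(
            lambda s: (s["ct_target"] - s["ct_reference"]).mean(),
            include_groups=False,
        )
        ddct = dct["endosperm"] - dct["leaf"]
        assert ddct == pytest.approx(-3.0)  # 2**3 = 8
        assert 2.0**-ddct == pytest.approx(8.0)

    def test_same_seed_gives_identical_tables(self):
        kw = dict(fold_by_tissue={"leaf": 1.0, "root": 2.0},
                  calibrator_tissue="leaf", seed=77, noise_sd=0.3)
        pd.testing.assert_frame_equal(
            simulate_qpcr("g", **kw), simulate_qpcr("g", **kw)
        )


class TestPaperFixture:
    def test_gene_funnel_composition(self, fixture):
        truth = fixture.truth
        assert len(truth) == 17
        assert (truth["n_snps"] == 0).sum() == 10
        informative = truth[truth["n_snps"] > 0]
        assert sorted(informative["n_snps"]) == sorted([1, 2, 19, 17, 3, 11, 2])
        assert (informative["endosperm_state"] == "MEG").sum() == 5

    def test_fixture_is_deterministic(self, fixture):
        from fvimprint import make_paper_fixture

        again = make_paper_fixture()
        assert again.haplotypes == fixture.haplotypes
        key = next(iter(fixture.hybrid_reads))
        assert again.hybrid_reads[key].reads == fixture.hybrid_reads[key].reads
        pd.testing.assert_frame_equal(again.ct_table, fixture.ct_table)

    def test_fixture_write_produces_expected_files(self, fixture, tmp_path):
        fixture.write(tmp_path)
        assert (tmp_path / "queries.faa").exists()
        assert (tmp_path / "proteome.faa").exists()
        assert len(list((tmp_path / "parents").glob("*.fasta"))) == 34
        assert len(list((tmp_path / "hybrids").glob("*.fasta"))) == 28
        manifest = pd.read_csv(tmp_path / "truth" / "snps.tsv", sep="\t")
        assert len(manifest) == 1 + 2 + 19 + 17 + 3 + 11 + 2
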