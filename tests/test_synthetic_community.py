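"""Ground-truth generator: determinism, conservation, model recovery."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from amgkit.quantify import community_ratio
from amgkit.seq_io import translate
from amgkit.synthetic_community import (
    SimConfig,
    evolve_codon_pair,
    plant_crispr_array,
    simulate_community,
    simulate_coverage,
    simulate_transcripts,
    write_community,
)


class TestSimulateCommunity:
    def test_amg_counts_within_configured_range(self, community, noise_free_config):
        lo, hi = noise_free_config.amg_per_phage_range
        per_phage = {}
        for g in community.manifest.genes:
            if g.planted_amg:
                per_phage[g.contig_id] = per_phage.get(g.contig_id, 0) + 1
        assert len(per_phage) == noise_free_config.n_phages
        assert all(lo <= n <= hi for n in per_phage.values())

    def test_lengths_respect_ranges(self, community, noise_free_config):
        for c in community.contigs:
            role = community.manifest.contig_roles[c.id]
            lo, hi = (
                noise_free_config.phage_len_range
                if role == "phage"
                else noise_free_config.host_len_range
            )
            assert lo <= c.length <= hi

    def test_empty_phage_set(self):
        cfg = SimConfig(seed=1, n_phages=0, n_hosts=2, host_len_range=(10_000, 12_000))
        comm = simulate_community(cfg)
        roles = set(comm.manifest.contig_roles.values())
        assert roles == {"host"}
        assert not comm.manifest.pairs and not comm.manifest.spacer_links

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(phage_len_range=(10_000, 5_000))

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(amg_family_weights={"DsrA": 0.5})

    def test_manifest_counts_match_gene_tables(self, community):
        table_ids = {g.gene_id for g in community.all_genes()}
        manifest_ids = {g.gene_id for g in community.manifest.genes}
        assert table_ids == manifest_ids

    def test_pairs_are_one_to_one_per_amg(self, community):
        amg_ids = {g.gene_id for g in community.manifest.genes if g.planted_amg}
        paired_phage = [p.phage_gene_id for p in community.manifest.pairs]
        assert sorted(paired_phage) == sorted(amg_ids)
        host_ids = [p.host_gene_id for p in community.manifest.pairs]
        assert len(set(host_ids)) == len(host_ids)

    def test_cds_translates_to_protein(self, community):
        for g in community.all_genes()[:50]:
            assert translate(g.cds) == g.protein

    def test_byte_identical_for_fixed_seed(self, tmp_path, noise_free_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            comm = simulate_community(noise_free_config)
            write_community(comm, d, config=noise_free_config)
        names = sorted(p.name for p in d1.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert sorted(match) == names and not mismatch and not errors

    def test_family_weights_recovered_chi_square(self):
        cfg = SimConfig(
            seed=23,
            n_phages=400,
            n_hosts=0,
            phage_len_range=(5_000, 8_000),
            crispr_spacers_per_host=0,
        )
        comm = simulate_community(cfg)
        counts = {}
        for g in comm.manifest.genes:
            if g.planted_amg:
                counts[g.family] = counts.get(g.family, 0) + 1
        n = sum(counts.values())
        assert n >= 400  # at least one AMG per phage
        fams = sorted(cfg.amg_family_weights)
        observed = [counts.get(f, 0) for f in fams]
        expected = [cfg.amg_family_weights[f] * n for f in fams]
        _stat, p = stats.chisquare(observed, expected)
        assert p > 1e-3


class TestSimulateCoverage:
    def test_zero_virocell_fraction_zeroes_phage_genes(self, noise_free_config):
        cfg = SimConfig(
            **{
                **noise_free_config.__dict__,
                "virocell_fraction": 0.0,
            }
        )
        comm = simulate_community(cfg)
        cov = simulate_coverage(comm.manifest, cfg)
        assert (cov.loc[cov["source"] == "phage", "coverage"] == 0).all()
        assert (cov.loc[cov["source"] == "host", "coverage"] > 0).all()

    @pytest.mark.parametrize(
        "v,R,expected",
        [(0.5, 1.0, 1 / 3), (1.0, 1.0, 1 / 2)],
    )
    def test_noise_free_ratio_matches_closed_form(self, v, R, expected):
        cfg = SimConfig(
            seed=5,
            n_phages=4,
            n_hosts=2,
            phage_len_range=(5_000, 9_000),
            host_len_range=(10_000, 16_000),
            coverage_noise=0.0,
            virocell_fraction=v,
            replication_factor=R,
            n_samples=1,
        )
        comm = simulate_community(cfg)
        cov = simulate_coverage(comm.manifest, cfg)
        for family in sorted({g.family for g in comm.manifest.family_genes()}):
            assert community_ratio(cov, "S1", family) == pytest.approx(
                expected, abs=1e-9
            )

    def test_noisy_ratio_within_three_standard_errors(self):
        cfg = SimConfig(
            seed=17,
            n_phages=25,
            n_hosts=5,
            phage_len_range=(5_000, 9_000),
            host_len_range=(10_000, 40_000),
            coverage_noise=0.3,
            amg_family_weights={"DsrC": 1.0},
            amg_per_phage_range=(4, 4),
            n_samples=1,
        )
        comm = simulate_community(cfg)
        cov = simulate_coverage(comm.manifest, cfg)
        sub = cov[cov["family"] == "DsrC"]
        assert len(sub) >= 200  # 100 phage + 100 host genes
        phage = sub.loc[sub["source"] == "phage", "coverage"].to_numpy()
        host = sub.loc[sub["source"] == "host", "coverage"].to_numpy()
        P, H = phage.sum(), host.sum()
        ratio = P / (P + H)
        # delta method on r = P/(P+H)
        var_p = phage.var(ddof=1) * len(phage)
        var_h = host.var(ddof=1) * len(host)
        se = np.sqrt(H**2 * var_p + P**2 * var_h) / (P + H) ** 2
        vR = cfg.virocell_fraction * cfg.replication_factor
        assert abs(ratio - vR / (vR + 1)) <= 3 * se


class TestSimulateTranscripts:
    def _mean_amg_fold(self, comm, cfg):
        counts = simulate_transcripts(comm.manifest, cfg)
        amg = counts[(counts["source"] == "phage")]
        pivot = amg.pivot_table(index="gene_id", columns="condition", values="count")
        pivot = pivot[pivot["background"] > 0]
        return (pivot["hydrothermal"] / pivot["background"]).mean(), len(pivot)

    def test_null_fold_gives_unit_ratio(self):
        cfg = SimConfig(seed=3, n_phages=10, n_hosts=2, condition_fold=1.0,
                        phage_len_range=(5_000, 9_000), host_len_range=(10_000, 30_000))
        comm = simulate_community(cfg)
        mean_fold, n = self._mean_amg_fold(comm, cfg)
        assert n >= 10
        assert mean_fold == pytest.approx(1.0, rel=0.15)

    def test_fold_of_fifteen_recovered_within_twenty_percent(self):
        cfg = SimConfig(seed=9, n_phages=25, n_hosts=2, condition_fold=15.0,
                        amg_per_phage_range=(2, 4),
                        phage_len_range=(5_000, 9_000), host_len_range=(10_000, 40_000))
        comm = simulate_community(cfg)
        mean_fold, n = self._mean_amg_fold(comm, cfg)
        assert n >= 50
        assert abs(mean_fold - 15.0) / 15.0 <= 0.20


class TestEvolveCodonPair:
    def test_zero_divergence_identical(self):
        a, b, _ = evolve_codon_pair(100, 0.5, 0.0, seed=1)
        assert a == b and len(a) == 300

    def test_sequences_are_stop_free(self):
        a, b, _ = evolve_codon_pair(200, 1.0, 0.5, seed=2)
        assert "*" not in translate(a, trim_stop=False)
        assert "*" not in translate(b, trim_stop=False)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            evolve_codon_pair(10, -0.1, 0.1, seed=0)


class TestPlantCrisprArray:
    def test_structure_and_truth(self):
        rng = np.random.default_rng(0)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 2_000))
        phage = "".join("ACGT"[i] for i in rng.integers(0, 4, 5_000))
        modified, truth = plant_crispr_array(
            genome, phage, rng, repeat_len=25, spacer_len=32, n_spacers=4
        )
        assert len(modified) == len(genome) + 5 * 25 + 4 * 32
        assert len(truth) == 4
        for t in truth:
            assert phage[t["origin"] : t["origin"] + 32] == t["sequence"]
            assert t["sequence"] in modified

    def test_zero_spacers_leaves_genome_unchanged(self):
        rng = np.random.default_rng(0)
        genome = "ACGT" * 100
        modified, truth = plant_crispr_array(genome, "ACGT" * 100, rng, n_spacers=0)
        assert modified == genome and truth == []

    def test_requested_mismatches_are_planted(self):
        rng = np.random.default_rng(3)
        phage = "".join("ACGT"[i] for i in rng.integers(0, 4, 3_000))
        _modified, truth = plant_crispr_array(
            "A" * 500, phage, rng, n_spacers=3, mismatches_per_spacer=3
        )
        for t in truth:
            original = phage[t["origin"] : t["origin"] + 32]
            hamming = sum(1 for x, y in zip(original, t["sequence"]) if x != y)
            assert hamming == 3
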