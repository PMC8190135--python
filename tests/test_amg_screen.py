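"""Motif validation, DsrC/TusE classes, viral-context rules, neighborhoods."""

import numpy as np
import pytest

from amgkit.amg_screen import (
    AMG_FAMILIES,
    MOTIF_CATALOG,
    REFERENCE_PROTEINS,
    MotifReport,
    classify_dsrc,
    extract_neighborhood,
    flag_amg_contamination,
    scan_motifs,
    score_viral_context,
    screen_contig,
)
from amgkit.seq_io import GeneRecord
from amgkit.synthetic_community import SimConfig, simulate_community

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# independent brute-force scan checker (mirrors the documented contract)
# ---------------------------------------------------------------------------

def brute_force_scan(protein: str, family: str) -> dict:
    """Window-by-window re-implementation of scan-mode semantics."""

    def matches_window(pattern, window, strict_only):
        for pc, wc in zip(pattern, window):
            if pc in "xX":
                continue
            if pc.isupper():
                if wc != pc:
                    return False
            elif not strict_only and wc != pc.upper():
                return False
        return True

    ref = REFERENCE_PROTEINS[family]
    groups: dict[int, list] = {}
    for m in MOTIF_CATALOG[family]:
        groups.setdefault(ref.motif_positions[m.motif_id], []).append(m)
    out = {}
    cursor = 0
    for start in sorted(groups):
        group_end = cursor
        for m in groups[start]:
            if len(m.pattern) < 2:
                continue
            hit = None
            for p in range(cursor, len(protein) - len(m.pattern) + 1):
                if matches_window(m.pattern, protein[p : p + len(m.pattern)], True):
                    hit = p
                    break
            if hit is None:
                out[m.motif_id] = (False, False, None)
            else:
                full = matches_window(
                    m.pattern, protein[hit : hit + len(m.pattern)], False
                )
                out[m.motif_id] = (True, full, hit)
                group_end = max(group_end, hit + len(m.pattern))
        cursor = group_end
    return out


class TestScanMotifs:
    def test_literal_soxd_embedding(self):
        report = scan_motifs("MKCAACHGYK", "SoxD", mode="scan")
        m = report.matches["soxD_cytc_CxxCHG"]
        assert m.strict_match and m.full_match and m.position == 2

    def test_literal_dsra_siroheme_embedding(self):
        report = scan_motifs("MKCAGAAACR", "DsrA", mode="scan")
        m = report.matches["dsrA_siroheme_CxgxxxC"]
        assert m.strict_match and m.full_match and m.position == 2

    def test_soxd_missing_both_motifs_not_validated(self):
        protein = "M" + "ALVTSNQIFWY" * 5  # filler only: no cytochrome motifs
        report = scan_motifs(protein, "SoxD", mode="scan")
        assert not report.matches["soxD_cytc_CxxCHG"].strict_match
        assert not report.matches["soxD_cytc_CMxxC"].strict_match
        assert report.family_call == "SoxD"
        assert not report.validated

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("", "DsrA")

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            scan_motifs("MAAA", "NifH")

    @pytest.mark.parametrize("family", AMG_FAMILIES)
    def test_scan_agrees_with_brute_force_on_random_proteins(self, family):
        rng = np.random.default_rng(sum(map(ord, family)))
        for _ in range(1_000):
            n = int(rng.integers(20, 150))
            protein = "".join(AA20[i] for i in rng.integers(0, 20, n))
            report = scan_motifs(protein, family, mode="scan")
            expected = brute_force_scan(protein, family)
            got = {
                mid: (m.strict_match, m.full_match, m.position)
                for mid, m in report.matches.items()
            }
            assert got == expected

    def test_planted_amgs_fully_recovered_in_both_modes(self, community):
        """Conservation probability 1.0 -> every planted AMG strict+full."""
        genes = {g.gene_id: g for g in community.all_genes()}
        planted = [t for t in community.manifest.genes if t.planted_amg]
        assert planted
        for t in planted:
            for mode in ("anchored", "scan"):
                report = scan_motifs(genes[t.gene_id].protein, t.family, mode=mode)
                assert report.validated, (t.gene_id, mode)
                assert all(m.full_match for m in report.matches.values())

    def test_anchored_mode_checks_single_residue_motifs(self):
        ref = REFERENCE_PROTEINS["SoxC"]
        report = scan_motifs(ref.sequence, "SoxC", mode="anchored")
        assert report.matches["soxC_active_D"].strict_match
        assert report.matches["soxC_active_R"].strict_match
        # break the aspartate
        pos = ref.motif_positions["soxC_active_D"]
        broken = ref.sequence[:pos] + "A" + ref.sequence[pos + 1 :]
        report = scan_motifs(broken, "SoxC", mode="anchored")
        assert not report.matches["soxC_active_D"].strict_match
        assert report.matches["soxC_active_R"].strict_match


class TestClassifyDsrc:
    def _report(self, klass):
        return MotifReport(
            protein_id="p",
            family_call="DsrC",
            matches={},
            dsrc_class=klass,
        )

    def test_printed_partition_yields_118_tusE_like(self):
        reports = (
            [self._report("both")] * 23
            + [self._report("second_only")] * 112
            + [self._report("first_only")] * 1
            + [self._report("neither")] * 5
        )
        part = classify_dsrc(reports)
        assert (part.both, part.second_only, part.first_only, part.neither) == (
            23,
            112,
            1,
            5,
        )
        assert part.tusE_like == 118
        assert part.total == 141

    def test_all_both_gives_zero_tusE(self):
        part = classify_dsrc([self._report("both")] * 7)
        assert part.tusE_like == 0 and part.both == 7

    def test_empty_input(self):
        part = classify_dsrc([])
        assert part.total == 0 and part.tusE_like == 0

    def test_partition_exhaustive_and_disjoint_on_planted_variants(self):
        cfg = SimConfig(
            seed=31,
            n_phages=12,
            n_hosts=0,
            amg_family_weights={"DsrC": 1.0},
            amg_per_phage_range=(2, 3),
            dsrc_class_weights={
                "both": 0.4,
                "second_only": 0.3,
                "first_only": 0.15,
                "neither": 0.15,
            },
            phage_len_range=(5_000, 9_000),
        )
        comm = simulate_community(cfg)
        genes = {g.gene_id: g for g in comm.all_genes()}
        truths = [t for t in comm.manifest.genes if t.planted_amg]
        reports = [
            scan_motifs(genes[t.gene_id].protein, "DsrC", mode="anchored")
            for t in truths
        ]
        part = classify_dsrc(reports)
        assert part.total == len(truths)
        assert part.tusE_like + part.both == part.total
        # anchored classification recovers each planted class
        for t, r in zip(truths, reports):
            assert r.dsrc_class == t.dsrc_class, t.gene_id


def _gene(label, keywords=(), idx=0):
    return GeneRecord(
        "c1",
        idx,
        idx * 400 + 1,
        idx * 400 + 300,
        "+",
        protein="M" + "A" * 60,
        annotation_label=label,
        keyword_terms=set(keywords),
    )


class TestViralContext:
    def test_stated_rule_phage(self):
        genes = (
            [_gene("viral-hallmark", ["terminase"], 0)]
            + [_gene("viral-like", idx=i) for i in range(1, 5)]
            + [_gene("microbial-like", idx=5)]
            + [_gene("unannotated", idx=i) for i in range(6, 10)]
        )
        v = score_viral_context(genes)
        assert v.verdict == "phage" and not v.lysogeny_flag
        assert v.n_genes == 10

    def test_integrase_keyword_sets_lysogeny_flag(self):
        genes = [
            _gene("viral-hallmark", ["terminase"], 0),
            _gene("viral-like", ["phage integrase"], 1),
        ]
        assert score_viral_context(genes).lysogeny_flag

    def test_all_microbial_no_hallmark_is_not_phage(self):
        genes = [_gene("microbial-like", idx=i) for i in range(10)]
        assert score_viral_context(genes).verdict == "not_phage"

    def test_counts_sum_to_total(self):
        genes = [
            _gene(l, idx=i)
            for i, l in enumerate(
                ["viral-hallmark", "viral-like", "microbial-like", "unannotated"] * 3
            )
        ]
        v = score_viral_context(genes)
        assert v.n_genes == len(genes)


class TestContamination:
    def _contig(self, integrase):
        genes = [_gene("microbial-like", idx=i) for i in range(5)]
        genes.append(_gene("microbial-like", ["dsrC sulfur"], 5))
        genes += [_gene("microbial-like", idx=i) for i in range(6, 9)]
        genes += [
            _gene("viral-like", ["integrase"] if integrase else ["helicase"], 9),
            _gene("unannotated", idx=10),
        ]
        return genes

    def test_dense_microbial_window_plus_integrase_flags(self):
        assert flag_amg_contamination(self._contig(True), 5)

    def test_no_integrase_means_no_flag(self):
        assert not flag_amg_contamination(self._contig(False), 5)

    def test_window_truncated_at_contig_start(self):
        genes = [
            _gene("microbial-like", idx=0),
            _gene("microbial-like", idx=1),
            _gene("microbial-like", ["dsrA sulfur"], 2),
            _gene("microbial-like", idx=3),
            _gene("viral-like", ["integrase"], 4),
        ]
        # 3 of 4 available neighbors microbial-like = 0.75 >= 0.7
        assert flag_amg_contamination(genes, 2)


class TestNeighborhood:
    def _genes(self, n):
        return [_gene("unannotated", idx=i) for i in range(n)]

    def test_full_window_returned(self):
        window = extract_neighborhood(self._genes(20), 7, k=5)
        assert [g.gene_index for g in window] == list(range(2, 13))

    def test_scaffold_end_rejected(self):
        assert extract_neighborhood(self._genes(20), 2, k=5) is None

    def test_exact_fit_accepted(self):
        window = extract_neighborhood(self._genes(11), 5, k=5)
        assert len(window) == 11


class TestScreenContig:
    def test_short_contig_rejected(self):
        assert screen_contig([_gene("viral-hallmark")], 4_999) is None

    def test_candidates_found_by_family_keyword(self, community):
        n_candidates = 0
        for c in community.contigs:
            if community.manifest.contig_roles[c.id] != "phage":
                continue
            verdict, rows = screen_contig(community.genes[c.id], c.length)
            assert verdict.verdict == "phage"
            n_candidates += len(rows)
        n_planted = sum(1 for g in community.manifest.genes if g.planted_amg)
        assert n_candidates == n_planted
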