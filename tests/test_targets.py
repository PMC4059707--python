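import pytest

from milksieve import (
    ScanConfig,
    SequenceRecord,
    consensus,
    make_target_fixture,
    miranda_scan,
    pita_scan,
    reverse_complement,
    rnahybrid_scan,
    scan_all,
)
from milksieve.targets import TargetSite

# T/C-only miRNA -> G/A-only site: the unstructured fixture has no
# self-structure at all, so its opening cost is exactly zero
MIRNA = "TCCTCCTTCCTCTCCTTCCTC"


@pytest.fixture(scope="module")
def fixtures():
    unstructured, span_u = make_target_fixture(MIRNA, "unstructured")
    hairpin, span_h = make_target_fixture(MIRNA, "hairpin")
    return unstructured, span_u, hairpin, span_h


class TestMiranda:
    def test_perfect_site_scores_255(self, model, fixtures):
        unstructured, span, _, _ = fixtures
        (site,) = miranda_scan("mir", MIRNA, unstructured, model)
        # 10 weighted positions at 4*5 plus 11 at 5
        assert site.align_score == pytest.approx(255.0)
        assert site.site_span == span

    def test_wobble_in_seed_is_discarded(self, model):
        # give miRNA position 4 a G so the complementary site can present U
        mirna = MIRNA[:3] + "G" + MIRNA[4:]
        site = list(reverse_complement(mirna))
        # seed pairs antiparallel: miRNA position p (1-based) pairs site index len-p
        site[len(site) - 4] = "T"  # G:U wobble at miRNA position 4 (inside seed 2-8)
        rec = SequenceRecord("t", "A" * 20 + "".join(site) + "A" * 20)
        assert miranda_scan("mir", mirna, rec, model) == []

    def test_score_threshold_is_strict(self, model, fixtures):
        unstructured, _, _, _ = fixtures
        config = ScanConfig(miranda_min_score=255.0)  # perfect site scores exactly 255
        assert miranda_scan("mir", MIRNA, unstructured, model, config) == []

    def test_polya_transcript_has_no_sites(self, model):
        rec = SequenceRecord("t", "A" * 80)
        assert miranda_scan("mir", MIRNA, rec, model) == []


class TestRNAhybrid:
    def test_perfect_site_found(self, model, fixtures):
        unstructured, span, _, _ = fixtures
        sites = rnahybrid_scan("mir", MIRNA, unstructured, model)
        assert any(s.site_span == span for s in sites)
        assert all(s.duplex_mfe <= -17.0 for s in sites)

    def test_mfe_threshold_keeps_exact_boundary(self, model, fixtures):
        unstructured, _, _, _ = fixtures
        (site,) = rnahybrid_scan("mir", MIRNA, unstructured, model)
        boundary = ScanConfig(rnahybrid_max_mfe=site.duplex_mfe)
        kept = rnahybrid_scan("mir", MIRNA, unstructured, model, boundary)
        assert [s.site_span for s in kept] == [site.site_span]
        below = ScanConfig(rnahybrid_max_mfe=site.duplex_mfe - 1e-6)
        assert rnahybrid_scan("mir", MIRNA, unstructured, model, below) == []

    def test_polya_transcript_has_no_sites(self, model):
        rec = SequenceRecord("t", "A" * 80)
        assert rnahybrid_scan("mir", MIRNA, rec, model) == []


class TestPita:
    def test_seed_mismatch_rejected_before_energy(self, model):
        mirna = MIRNA
        site = list(reverse_complement(mirna))
        site[len(site) - 5] = "T"  # breaks WC complementarity at seed position 5
        rec = SequenceRecord("t", "A" * 20 + "".join(site) + "A" * 20)
        assert pita_scan("mir", mirna, rec, model) == []

    def test_unstructured_ddg_equals_duplex_mfe(self, model, fixtures):
        unstructured, span, _, _ = fixtures
        (site,) = pita_scan("mir", MIRNA, unstructured, model)
        assert site.site_span == span
        assert site.ddg == pytest.approx(site.duplex_mfe)

    def test_hairpin_strictly_worsens_ddg(self, model, fixtures):
        unstructured, _, hairpin, _ = fixtures
        loose = ScanConfig(pita_max_ddg=1e9)
        (open_site,) = pita_scan("mir", MIRNA, unstructured, model, loose)
        hairpin_sites = pita_scan("mir", MIRNA, hairpin, model, loose)
        assert hairpin_sites
        assert min(s.ddg for s in hairpin_sites) > open_site.ddg


class TestConsensus:
    def _site(self, method, tid="t1", score=0.0, mfe=-20.0, ddg=-15.0):
        return TargetSite(
            mirna_id="mir",
            transcript_id=tid,
            region="3UTR",
            site_span=(0, 21),
            align_score=score,
            duplex_mfe=mfe,
            ddg=ddg,
            seed_ok=True,
            method=method,
        )

    def test_two_method_target_excluded(self, model):
        per_method = {
            "miranda": [self._site("miranda", score=200)],
            "rnahybrid": [self._site("rnahybrid")],
            "pita": [],
        }
        assert consensus("mir", per_method) == []

    def test_ranking_by_score_then_mfe(self):
        per_method = {
            "miranda": [
                self._site("miranda", "t1", score=180, mfe=-18),
                self._site("miranda", "t2", score=150, mfe=-30),
                self._site("miranda", "t3", score=150, mfe=-20),
            ],
            "rnahybrid": [
                self._site("rnahybrid", t) for t in ("t1", "t2", "t3")
            ],
            "pita": [self._site("pita", t) for t in ("t1", "t2", "t3")],
        }
        ranked = consensus("mir", per_method)
        assert [c.transcript_id for c in ranked] == ["t1", "t2", "t3"]

    def test_top_k_truncation(self):
        ids = [f"t{i}" for i in range(30)]
        per_method = {
            m: [self._site(m, t, score=float(i)) for i, t in enumerate(ids)]
            for m in ("miranda", "rnahybrid", "pita")
        }
        assert len(consensus("mir", per_method, top_k=25)) == 25

    def test_planted_site_recovered_by_all_and_ranks_first(self, model, fixtures):
        unstructured, span, _, _ = fixtures
        decoy = SequenceRecord("decoy", "A" * 70)
        per_method = scan_all("mir", MIRNA, [unstructured, decoy], model)
        for method, sites in per_method.items():
            assert any(s.site_span == span for s in sites), method
        ranked = consensus("mir", per_method)
        assert ranked and ranked[0].transcript_id == "fixture_unstructured"
        assert ranked[0].sites[0].site_span == span

    def test_consensus_subset_of_each_method(self, model, fixtures):
        unstructured, _, hairpin, _ = fixtures
        per_method = scan_all("mir", MIRNA, [unstructured, hairpin], model)
        ranked = consensus("mir", per_method)
        for c in ranked:
            for method in ("miranda", "rnahybrid", "pita"):
                assert any(
                    s.transcript_id == c.transcript_id for s in per_method[method]
                )
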