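import numpy as np
import pandas as pd
import pytest
from scipy import special

from epimediate.datamodel import ProbeAnnotation
from epimediate.enrichment import over_representation, probes_to_genes, top_probes
from epimediate.mediation import MediationEstimate


def _est(probe, p, met="met000"):
    return MediationEstimate(
        probe_id=probe, metabolite_id=met, direction="dnam_psv",
        log_nie=-0.3, log_nde=0.0, log_te=-0.3, se_log_nie=0.1, p_nie=p,
    )


def hypergeom_tail_brute(k, N, K, n):
    """P[X >= k] by exhaustive pmf summation (binomial coefficients)."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (special.comb(K, x, exact=True) * special.comb(N - K, n - x, exact=True))
    return total / special.comb(N, n, exact=True)


def _annotation(mapping):
    probes = list(mapping)
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chromosome": "chr1",
                "position": np.arange(1, len(probes) + 1),
                "island_relation": "OpenSea",
                "gene_symbol": [mapping[p] for p in probes],
            },
            index=pd.Index(probes, name="probe_id"),
        )
    )


class TestTopProbes:
    def test_shared_probe_appears_once(self):
        ests = [_est("cgA", 0.001, f"met{i}") for i in range(5)]
        assert top_probes(ests, k=10) == ["cgA"]

    def test_k_exceeding_unique_returns_all(self):
        ests = [_est(f"cg{i}", 0.01 * (i + 1)) for i in range(4)]
        assert top_probes(ests, k=100) == [f"cg{i}" for i in range(4)]

    def test_tie_block_stable_under_permutation(self, rng):
        ests = [_est(f"cg{i:03d}", 0.02) for i in range(20)]
        ests += [_est(f"cg{i:03d}", 0.001) for i in range(20, 25)]
        base = top_probes(ests, k=10)
        for _ in range(5):
            shuffled = list(rng.permutation(ests))
            assert top_probes(shuffled, k=10) == base
        # ties broken lexicographically after the 5 clear winners
        assert base[:5] == [f"cg{i:03d}" for i in range(20, 25)]
        assert base[5:] == [f"cg{i:03d}" for i in range(5)]


class TestProbesToGenes:
    def test_two_probes_same_gene_deduplicated(self):
        ann = _annotation({"cg1": "GENE1", "cg2": "GENE1", "cg3": "GENE2"})
        assert probes_to_genes(["cg1", "cg2", "cg3"], ann) == ["GENE1", "GENE2"]

    def test_empty_gene_field_excluded(self):
        ann = _annotation({"cg1": "GENE1", "cg2": ""})
        assert probes_to_genes(["cg1", "cg2"], ann) == ["GENE1"]

    def test_unknown_probe_dropped(self):
        ann = _annotation({"cg1": "GENE1"})
        assert probes_to_genes(["cg1", "cgX"], ann) == ["GENE1"]


class TestOverRepresentation:
    def _universe(self, n=1000):
        return [f"G{i:04d}" for i in range(n)]

    def test_expected_and_fold_forced_by_definitions(self):
        # universe 1000, analysis 50, pathway 40 in reference, 6 observed
        ref = self._universe(1000)
        pathway = ref[:40]
        analysis = ref[:6] + ref[100:144]     # 6 hits + 44 non-pathway genes
        rows = over_representation(analysis, ref, {"P": pathway})
        r = rows[0]
        assert (r.n_analysis, r.n_reference) == (6, 40)
        assert r.expected == pytest.approx(2.0)
        assert r.fold == pytest.approx(3.0)

    def test_p_matches_exhaustive_tail_sum(self):
        ref = self._universe(60)
        analysis = ref[:12]
        gmt = {"A": ref[:8], "B": ref[4:24], "C": ref[30:45]}
        rows = over_representation(analysis, ref, gmt, min_ref=1, min_analysis=0)
        for r in rows:
            brute = hypergeom_tail_brute(r.n_analysis, 60, r.n_reference, 12)
            assert r.p == pytest.approx(brute, rel=1e-10)

    def test_size_exclusions_remove_intended_pathways(self):
        ref = self._universe(200)
        analysis = ref[:10]
        gmt = {
            "small_ref": ref[:4],            # 4 reference genes -> excluded (<5)
            "one_hit": ref[9:30],            # 1 analysis gene -> excluded (<2)
            "keeps": ref[:20],               # 10 hits, 20 ref genes -> retained
        }
        rows = over_representation(analysis, ref, gmt)
        assert [r.pathway for r in rows] == ["keeps"]
        # literal conjunction mode: excluded only when BOTH bounds fail
        rows_both = over_representation(analysis, ref, gmt, filter_mode="both")
        assert {r.pathway for r in rows_both} == {"small_ref", "one_hit", "keeps"}

    def test_expected_counts_sum_identity(self):
        ref = self._universe(500)
        rng = np.random.default_rng(3)
        analysis = list(rng.choice(ref, size=40, replace=False))
        gmt = {f"P{k}": list(rng.choice(ref, size=rng.integers(5, 60), replace=False))
               for k in range(12)}
        rows = over_representation(analysis, ref, gmt, min_ref=1, min_analysis=0)
        total_expected = sum(r.expected for r in rows)
        total_ref = sum(r.n_reference for r in rows)
        assert total_expected == pytest.approx(len(analysis) / len(ref) * total_ref, rel=1e-12)

    def test_p_monotone_in_observed_count(self):
        # fixed margins (universe 1000, pathway 50, analysis 100): more
        # observed hits must mean smaller upper-tail p
        ref = self._universe(1000)
        pathway = ref[:50]
        tails = []
        for k in range(2, 12):
            analysis = ref[:k] + ref[500:600 - k]
            rows = over_representation(analysis, ref, {"P": pathway})
            assert rows[0].n_analysis == k
            tails.append(rows[0].p)
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_invariant_to_gene_order_in_gmt(self, rng):
        ref = self._universe(300)
        analysis = ref[:25]
        genes = ref[:60]
        rows1 = over_representation(analysis, ref, {"P": genes})
        rows2 = over_representation(analysis, ref, {"P": list(rng.permutation(genes))})
        assert rows1[0] == rows2[0]

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError, match="reference"):
            over_representation(["A"], [], {"P": ["A"]})
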