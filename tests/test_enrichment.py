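"""Hypergeometric / Wallenius GO over-representation."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from coexflow.enrichment import (
    hypergeom_enrich,
    length_bias_weights,
    wallenius_enrich,
)

TERM = "GO:0000001"


def exhaustive_tail(N, K, n, k):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(n, K) + 1)
        if n - i <= N - K
    ) / comb(N, n)


def _setting(N, K, n):
    background = {f"t{i:03d}" for i in range(N)}
    ordered = sorted(background)
    ann = {t: {TERM} for t in ordered[:K]}
    study = set(ordered[K - min(K, n) :][: n])  # arbitrary fixed subset
    return background, ann, study


class TestHypergeom:
    def test_worked_case(self):
        # N=20, K=5, n=5, k=4 -> 76/15504
        background = {f"t{i}" for i in range(20)}
        annotated = set(sorted(background)[:5])
        ann = {t: {TERM} for t in annotated}
        study = set(sorted(annotated)[:4]) | {sorted(background - annotated)[0]}
        res = hypergeom_enrich(study, background, ann)
        assert res.iloc[0]["p"] == pytest.approx(76 / 15504, abs=1e-12)
        assert res.iloc[0]["enriched"]

    @pytest.mark.parametrize("N,K,n", [(10, 3, 4), (20, 5, 5), (25, 10, 8), (15, 15, 6)])
    def test_matches_exhaustive_enumeration(self, N, K, n):
        background = {f"t{i:03d}" for i in range(N)}
        ordered = sorted(background)
        ann = {t: {TERM} for t in ordered[:K]}
        rng = np.random.default_rng(N * 100 + K)
        study = set(rng.choice(ordered, size=n, replace=False))
        res = hypergeom_enrich(study, background, ann)
        k = len(study & set(ordered[:K]))
        assert res.iloc[0]["p"] == pytest.approx(exhaustive_tail(N, K, n, k), abs=1e-12)

    def test_study_equal_background_is_degenerate(self):
        background = {f"t{i}" for i in range(10)}
        ann = {t: {TERM} for t in sorted(background)[:4]}
        res = hypergeom_enrich(background, background, ann)
        assert res.iloc[0]["k"] == res.iloc[0]["K"]
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        background = {f"t{i}" for i in range(10)}
        ordered = sorted(background)
        ann = {ordered[0]: {TERM}}
        res = hypergeom_enrich(set(ordered[5:]), background, ann)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_study_outside_background_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich({"x"}, {"a", "b"}, {"a": {TERM}})

    def test_monotone_in_k(self):
        ps = [exhaustive_tail(20, 8, 6, k) for k in range(0, 7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bh_qvalues_bounded_below_by_p(self):
        background = {f"t{i:02d}" for i in range(30)}
        ordered = sorted(background)
        ann = {}
        for j, t in enumerate(ordered):
            ann[t] = {f"GO:{(j % 5) + 1:07d}"}
        study = set(ordered[:10])
        res = hypergeom_enrich(study, background, ann)
        assert (res["q"] >= res["p"] - 1e-15).all()
        assert res["p"].is_monotonic_increasing


class TestWallenius:
    def test_equal_lengths_match_central_exactly(self):
        background = {f"t{i:03d}" for i in range(200)}
        ordered = sorted(background)
        ann = {t: {TERM} for t in ordered[::3]}
        study = set(ordered[:40])
        lengths = pd.Series(500.0, index=ordered)
        a = hypergeom_enrich(study, background, ann)
        b = wallenius_enrich(study, background, ann, lengths)
        assert np.abs(a["p"].to_numpy() - b["p"].to_numpy()).max() <= 1e-9

    def test_length_biased_term_is_penalized(self):
        # study membership increases with length and the term is annotated
        # preferentially on long transcripts: the corrected p must be larger
        rng = np.random.default_rng(5)
        ordered = [f"t{i:03d}" for i in range(300)]
        background = set(ordered)
        lengths = pd.Series(np.linspace(200, 5000, 300), index=ordered)
        sel_p = (lengths - lengths.min()) / (lengths.max() - lengths.min())
        study = {t for t in ordered if rng.random() < 0.6 * sel_p[t]}
        ann = {t: {TERM} for t in ordered[200:]}  # the longest third
        central = hypergeom_enrich(study, background, ann)
        corrected = wallenius_enrich(study, background, ann, lengths)
        assert corrected.iloc[0]["p"] > central.iloc[0]["p"]

    def test_corrected_tail_matches_weighted_urn_monte_carlo(self):
        # small urn where the Wallenius tail can be checked by simulating
        # length-weighted sampling without replacement
        ordered = [f"t{i:02d}" for i in range(40)]
        background = set(ordered)
        lengths = pd.Series(
            np.r_[np.full(20, 300.0), np.full(20, 3000.0)], index=ordered
        )
        annotated = set(ordered[20:])  # the long ones
        ann = {t: {TERM} for t in annotated}
        rng = np.random.default_rng(11)
        study = set(rng.choice(ordered[20:], 10, replace=False)) | set(
            rng.choice(ordered[:20], 5, replace=False)
        )
        res = wallenius_enrich(study, background, ann, lengths)
        k, n = int(res.iloc[0]["k"]), int(res.iloc[0]["n"])
        w = length_bias_weights(study, background, lengths)
        odds = w[sorted(annotated)].mean() / w[sorted(background - annotated)].mean()
        hits = 0
        reps = 4000
        for _ in range(reps):
            weights = np.where([t in annotated for t in ordered], odds, 1.0).astype(float)
            drawn_ann = 0
            alive = np.ones(len(ordered), bool)
            for _draw in range(n):
                p = weights * alive
                p = p / p.sum()
                pick = rng.choice(len(ordered), p=p)
                alive[pick] = False
                drawn_ann += ordered[pick] in annotated
            hits += drawn_ann >= k
        mc = hits / reps
        se = np.sqrt(mc * (1 - mc) / reps) + 1e-3
        assert res.iloc[0]["p"] == pytest.approx(mc, abs=4 * se)

    def test_zero_overlap_gives_p_one(self):
        ordered = [f"t{i}" for i in range(10)]
        lengths = pd.Series(np.linspace(100, 1000, 10), index=ordered)
        ann = {ordered[0]: {TERM}}
        res = wallenius_enrich(set(ordered[5:]), set(ordered), ann, lengths)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_missing_lengths_fall_back_to_central(self, caplog):
        background = {f"t{i}" for i in range(10)}
        ann = {t: {TERM} for t in sorted(background)[:3]}
        with caplog.at_level("WARNING"):
            res = wallenius_enrich(set(sorted(background)[:5]), background, ann, None)
        want = hypergeom_enrich(set(sorted(background)[:5]), background, ann)
        assert res.iloc[0]["p"] == want.iloc[0]["p"]


class TestEnrichClusters:
    def test_results_ordered_and_order_invariant(self):
        from coexflow.network import ClusterSet

        ordered = [f"t{i:02d}" for i in range(60)]
        background = set(ordered)
        ann = {t: {TERM} for t in ordered[:20]}
        ann.update({t: ann.get(t, set()) | {"GO:0000002"} for t in ordered[40:]})
        cs = ClusterSet(
            clusters={0: set(ordered[:20]), 1: set(ordered[20:40])},
            unassigned=set(ordered[40:]),
            summary=pd.DataFrame(),
        )
        from coexflow.enrichment import enrich_clusters

        res = enrich_clusters(cs, ann, background)
        assert list(res["cluster"]) == sorted(res["cluster"])
        within = res[res.cluster == 0]
        assert within["p"].is_monotonic_increasing

    def test_cluster_without_annotated_members_skipped(self, caplog):
        from coexflow.enrichment import enrich_clusters
        from coexflow.network import ClusterSet

        cs = ClusterSet(clusters={0: {"x", "y"}}, unassigned=set(), summary=pd.DataFrame())
        with caplog.at_level("WARNING"):
            res = enrich_clusters(cs, {"a": {TERM}}, {"a", "b"})
        assert res.empty
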