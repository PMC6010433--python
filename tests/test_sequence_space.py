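"""PCA space, component selection, profile extraction, scoring, metrics."""

import itertools
import math

import numpy as np
import pytest

from ligasespace import (
    Msa,
    SyntheticConfig,
    encode,
    evaluate,
    extract_profile,
    fit_sequence_space,
    generate,
    match_score,
    normalize_and_impute,
    rank_components,
    reference_numbering,
)
from ligasespace.properties import EncodedMatrix
from ligasespace.sequence_space import (
    ClassificationMetrics,
    LigaseProfile,
    MatchResult,
    ProfilePosition,
    SequenceSpace,
    SequenceSpaceError,
    _holm,
)


def _space_from_matrix(X: np.ndarray) -> SequenceSpace:
    enc = EncodedMatrix(np.asarray(X, dtype=float), [f"s{i}" for i in range(len(X))],
                        n_columns=X.shape[1] // 5 or 1)
    return fit_sequence_space(enc)


def _pca_oracle(X: np.ndarray):
    """Brute-force covariance eigendecomposition (independent of the SVD path)."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestPca:
    @pytest.mark.parametrize("n,p,seed", [(4, 3, 0), (8, 6, 1), (6, 5, 2), (8, 6, 3), (5, 6, 4)])
    def test_agrees_with_eigendecomposition_oracle(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        space = _space_from_matrix(X)
        evals, evecs = _pca_oracle(X)
        k = min(n - 1, X.shape[1])
        assert np.allclose(space.explained_variance, np.clip(evals[:k], 0, None), atol=1e-8)
        for c in range(k):
            if evals[c] < 1e-10:
                continue
            dot = abs(np.dot(space.loadings[:, c], evecs[:, c]))
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_identical_rows_give_zero_variance_and_scores(self):
        X = np.tile(np.arange(10.0), (4, 1))
        space = _space_from_matrix(X)
        assert np.allclose(space.explained_variance, 0.0, atol=1e-12)
        assert np.allclose(space.scores, 0.0, atol=1e-10)

    def test_two_cloud_axis_matches_closed_form(self):
        # two clouds displaced along (1, 1)/sqrt(2): PC1 is the closed-form
        # leading eigenvector of the 2x2 covariance
        rng = np.random.default_rng(5)
        a = rng.normal(scale=0.05, size=(20, 2)) + [3, 3]
        b = rng.normal(scale=0.05, size=(20, 2))
        X = np.hstack([np.vstack([a, b]), np.zeros((40, 3))])
        space = _space_from_matrix(X)
        evals, evecs = _pca_oracle(X)
        assert abs(np.dot(space.loadings[:, 0], evecs[:, 0])) == pytest.approx(1.0, abs=1e-8)
        assert abs(abs(space.loadings[0, 0]) - 1 / math.sqrt(2)) < 0.05

    def test_reconstruction_identity(self, default_synthetic):
        _, msa, _ = default_synthetic
        enc = normalize_and_impute(encode(msa))
        space = fit_sequence_space(enc)
        recon = space.scores @ space.loadings.T + space.center
        assert np.allclose(recon, enc.values, atol=1e-6)

    def test_total_variance_conserved(self, default_synthetic):
        _, msa, _ = default_synthetic
        enc = normalize_and_impute(encode(msa))
        space = fit_sequence_space(enc)
        total = ((enc.values - enc.values.mean(axis=0)) ** 2).sum() / (len(msa) - 1)
        assert space.explained_variance.sum() == pytest.approx(total, abs=1e-8)

    def test_loadings_orthonormal_and_variance_nonincreasing(self, default_synthetic):
        _, msa, _ = default_synthetic
        space = fit_sequence_space(normalize_and_impute(encode(msa)))
        gram = space.loadings.T @ space.loadings
        assert np.allclose(gram, np.eye(space.n_components), atol=1e-8)
        assert (np.diff(space.explained_variance) <= 1e-10).all()

    def test_missing_cells_rejected(self):
        X = np.full((4, 5), np.nan)
        enc = EncodedMatrix(X, list("abcd"), 1)
        with pytest.raises(SequenceSpaceError, match="normalize_and_impute"):
            fit_sequence_space(enc)


def _rank_sum_enumeration_p(u_observed: float, n1: int, n2: int) -> float:
    """Exact two-sided rank-sum p by enumerating group-1 rank assignments."""
    ranks = range(1, n1 + n2 + 1)
    us = []
    for combo in itertools.combinations(ranks, n1):
        r1 = sum(combo)
        us.append(r1 - n1 * (n1 + 1) / 2)
    us = np.array(us)
    lo = (us <= u_observed).mean()
    hi = (us >= u_observed).mean()
    return min(1.0, 2 * min(lo, hi))


class TestRankComponents:
    def _space_with_scores(self, scores):
        scores = np.asarray(scores, dtype=float)
        n, k = scores.shape
        return SequenceSpace(
            ids=tuple(f"s{i}" for i in range(n)),
            scores=scores,
            loadings=np.eye(k),
            explained_variance=scores.var(axis=0, ddof=1),
            center=np.zeros(k),
            n_columns=1,
        )

    def _labels(self, n_lig, n_pro):
        labels = {f"s{i}": "ligase" for i in range(n_lig)}
        labels.update({f"s{i + n_lig}": "protease" for i in range(n_pro)})
        return labels

    def test_complete_6v12_separation_matches_exact_enumeration(self):
        scores = np.concatenate([np.arange(6) + 100.0, np.arange(12)])[:, None]
        space = self._space_with_scores(scores)
        seps = rank_components(space, self._labels(6, 12), max_components=1)
        expected = 2 / math.comb(18, 6)
        assert seps[0].p_value == pytest.approx(expected, rel=1e-9)
        assert seps[0].p_value == pytest.approx(
            _rank_sum_enumeration_p(seps[0].statistic, 6, 12), rel=1e-9
        )
        assert seps[0].selected

    def test_partial_separation_matches_enumeration(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(18, 1))
        scores[:6] += 1.0
        space = self._space_with_scores(scores)
        seps = rank_components(space, self._labels(6, 12), max_components=1)
        assert seps[0].p_value == pytest.approx(
            _rank_sum_enumeration_p(seps[0].statistic, 6, 12), rel=1e-9
        )

    def test_identical_distributions_not_selected(self):
        scores = np.concatenate([np.arange(9.0), np.arange(9.0)])[:, None]
        space = self._space_with_scores(scores)
        seps = rank_components(space, self._labels(9, 9), max_components=1)
        assert seps[0].p_value > 0.9 and not seps[0].selected

    def test_alpha_zero_selects_nothing(self):
        scores = np.concatenate([np.arange(6) + 100.0, np.arange(12)])[:, None]
        space = self._space_with_scores(scores)
        seps = rank_components(space, self._labels(6, 12), alpha=0.0, max_components=1)
        assert not any(s.selected for s in seps)

    def test_selected_implies_raw_p_below_alpha(self):
        rng = np.random.default_rng(7)
        space = self._space_with_scores(rng.normal(size=(18, 6)))
        seps = rank_components(space, self._labels(6, 12))
        for s in seps:
            if s.selected:
                assert s.p_value < 0.05
            assert s.p_adjusted >= s.p_value - 1e-15

    def test_insufficient_labels_error(self):
        space = self._space_with_scores(np.arange(4.0)[:, None])
        with pytest.raises(SequenceSpaceError, match=">=2"):
            rank_components(space, {"s0": "ligase", "s1": "protease", "s2": "protease"})

    def test_holm_adjustment_against_direct_formula(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = _holm(p)
        assert adj == pytest.approx([0.04, 0.09, 0.09, 0.5])


class TestProfileAndMatch:
    def test_planted_columns_dominate_top_weights(self):
        config = SyntheticConfig(seed=42, n_unknown=0, n_diagnostic=10,
                                 signal_fidelity=1.0, mla_mode="neutral")
        msa, truth = generate(config)
        enc = normalize_and_impute(encode(msa))
        space = fit_sequence_space(enc)
        seps = rank_components(space, msa.labels)
        profile = extract_profile(space, seps, msa, k=10)
        assert {p.column for p in profile.positions} == set(truth.diagnostic_columns)

    def test_default_profile_size_is_16(self, default_synthetic):
        _, msa, _ = default_synthetic
        enc = normalize_and_impute(encode(msa))
        space = fit_sequence_space(enc)
        seps = rank_components(space, msa.labels)
        profile = extract_profile(space, seps, msa)
        assert profile.size == 16
        weights = [p.weight for p in profile.positions]
        assert weights == sorted(weights, reverse=True)

    def test_ideal_residue_is_ligase_mode(self):
        records = tuple(
            [("L%d" % i, "VA") for i in range(5)] + [("L5", "IA")]
            + [("P%d" % i, "DA") for i in range(4)]
        )
        labels = {rid: ("ligase" if rid.startswith("L") else "protease") for rid, _ in records}
        msa = Msa(records, labels)
        enc = normalize_and_impute(encode(msa))
        space = fit_sequence_space(enc)
        profile = extract_profile(space, [0], msa, k=1)
        assert profile.positions[0].ideal == "V"

    def test_reference_numbering_attached(self, default_synthetic):
        _, msa, _ = default_synthetic
        colmap = reference_numbering(msa, msa.ids[0])
        enc = normalize_and_impute(encode(msa))
        space = fit_sequence_space(enc)
        seps = rank_components(space, msa.labels)
        profile = extract_profile(space, seps, msa, colmap=colmap)
        for pos in profile.positions:
            assert pos.ref_number == colmap.col_to_ref.get(pos.column)

    def test_k_beyond_columns_rejected(self, default_synthetic):
        _, msa, _ = default_synthetic
        space = fit_sequence_space(normalize_and_impute(encode(msa)))
        with pytest.raises(SequenceSpaceError):
            extract_profile(space, [0], msa, k=msa.n_columns + 1)

    def test_profile_json_roundtrip(self, tmp_path, default_synthetic):
        _, msa, _ = default_synthetic
        space = fit_sequence_space(normalize_and_impute(encode(msa)))
        seps = rank_components(space, msa.labels)
        profile = extract_profile(space, seps, msa)
        path = tmp_path / "profile.json"
        profile.to_json(path)
        assert LigaseProfile.from_json(path) == profile


def _profile_of(ideals_by_column, threshold=0.25):
    positions = tuple(
        ProfilePosition(col, None, float(len(ideals_by_column) - i), ideal)
        for i, (col, ideal) in enumerate(sorted(ideals_by_column.items()))
    )
    return LigaseProfile(positions, threshold=threshold)


class TestMatchScore:
    def test_full_match_scores_one(self):
        profile = _profile_of({i: "A" for i in range(16)})
        result = match_score("A" * 16, profile)
        assert result.score == 1.0 and result.predicted_class == "ligase"

    def test_quarter_match_is_ligase_at_closed_threshold(self):
        profile = _profile_of({i: "A" for i in range(16)})
        seq = "A" * 4 + "C" * 12
        result = match_score(seq, profile)
        assert result.n_match == 4
        assert result.score == 0.25
        assert result.predicted_class == "ligase"

    def test_zero_match_is_protease(self):
        profile = _profile_of({i: "A" for i in range(16)})
        assert match_score("C" * 16, profile).predicted_class == "protease"

    def test_deletion_matches_deletion(self):
        profile = _profile_of({0: "-", 1: "A"})
        assert match_score("-A", profile).n_match == 2

    def test_monotone_in_matching_positions(self):
        profile = _profile_of({i: "A" for i in range(8)})
        prev = -1
        for k in range(9):
            seq = "A" * k + "C" * (8 - k)
            score = match_score(seq, profile).n_match
            assert score > prev
            prev = score

    def test_short_sequence_rejected(self):
        profile = _profile_of({5: "A"})
        with pytest.raises(SequenceSpaceError):
            match_score("AAA", profile)


class TestEvaluate:
    def _preds(self, spec):
        # spec: list of (id, predicted_class)
        return [MatchResult(rid, 4, 16, cls) for rid, cls in spec]

    def test_confusion_arithmetic(self):
        truth = {f"L{i}": "ligase" for i in range(6)}
        truth.update({f"P{i}": "protease" for i in range(12)})
        preds = self._preds(
            [(f"L{i}", "ligase") for i in range(6)]
            + [(f"P{i}", "protease") for i in range(11)]
            + [("P11", "ligase")]
        )
        m = evaluate(preds, truth)
        assert (m.TP, m.FP, m.TN, m.FN) == (6, 1, 11, 0)
        assert m.accuracy == pytest.approx(17 / 18)

    def test_printed_specificity_formula_is_verbatim(self):
        m = ClassificationMetrics(TP=6, FP=0, TN=12, FN=0)
        assert m.accuracy == 1.0
        assert m.specificity_standard == 1.0
        assert m.specificity_printed == pytest.approx(2.0)

    def test_unknowns_excluded_and_empty_truth_rejected(self):
        preds = self._preds([("a", "ligase")])
        with pytest.raises(SequenceSpaceError):
            evaluate(preds, {"a": "unknown"})
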