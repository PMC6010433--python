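"""PCA sequence space, ligase-predictive profile and match-score classifier.

The numericised alignment is decomposed by PCA into covarying sets of
residue properties.  Components on which known ligases and known proteases
separate (exact Wilcoxon rank-sum test on the component coordinates) are
pooled: per alignment column the absolute loadings over the selected
components and the five properties are summed, the top-weighted columns
become the ligase-predictive positions, and the modal residue among known
ligases at each position is its "ideal" ligase residue.  A sequence is then
scored by the fraction of positions carrying the ideal residue and called
ligase-type when the fraction reaches a threshold (default >=25%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .msa import AMINO_ACIDS, GAP, ColumnMap, Msa
from .properties import EncodedMatrix, N_PROPERTIES, PHYSICAL, default_property_table


class SequenceSpaceError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceSpace:
    """A fitted PCA decomposition of the encoded alignment.

    ``scores`` are per-sequence coordinates, ``loadings`` the orthonormal
    feature weights (features x components), ``explained_variance`` the
    non-increasing per-component variances and ``center`` the per-feature
    mean removed before decomposition.
    """

    ids: tuple[str, ...]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    center: np.ndarray
    n_columns: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_sequence_space(encoded: EncodedMatrix) -> SequenceSpace:
    """Deterministic PCA of the column-centered encoded matrix.

    Uses SVD without variance scaling (the descriptors are already
    normalised).  Component signs are fixed so that each loading column's
    largest-magnitude entry is positive, making outputs reproducible
    across runs and platforms.
    """
    if encoded.n_sequences < 3:
        raise SequenceSpaceError("need at least 3 sequences")
    if not encoded.is_complete:
        raise SequenceSpaceError(
            "matrix has missing cells; run normalize_and_impute first"
        )
    X = encoded.values
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(encoded.n_sequences - 1, X.shape[1])
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    loadings = Vt.T
    # sign convention: largest-|.| loading entry positive per component
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xc @ loadings
    explained = s**2 / max(encoded.n_sequences - 1, 1)
    return SequenceSpace(
        tuple(encoded.ids), scores, loadings, explained, center, encoded.n_columns
    )


@dataclass(frozen=True)
class ComponentSeparation:
    """Ligase-vs-protease separation of one principal component."""

    component_index: int
    statistic: float  # Mann-Whitney U for the ligase group
    p_value: float  # exact two-sided rank-sum p
    p_adjusted: float  # Holm step-down adjusted (equal to p_value if none)
    selected: bool


def rank_components(
    space: SequenceSpace,
    labels: dict[str, str],
    alpha: float = 0.05,
    max_components: int | None = None,
    correction: str = "holm",
) -> list[ComponentSeparation]:
    """Test each leading component for ligase/protease separation.

    An exact two-sided Wilcoxon rank-sum (Mann-Whitney) test compares the
    component coordinates of known ligases against known proteases;
    unknowns are ignored.  With ``correction='holm'`` (default) the
    selection controls the family-wise chance of flagging any component of
    a signal-free alignment at ``alpha``; ``'none'`` selects on raw
    p-values.
    """
    if correction not in ("holm", "none"):
        raise SequenceSpaceError(f"unknown correction {correction!r}")
    lig = [i for i, rid in enumerate(space.ids) if labels.get(rid) == "ligase"]
    pro = [i for i, rid in enumerate(space.ids) if labels.get(rid) == "protease"]
    if len(lig) < 2 or len(pro) < 2:
        raise SequenceSpaceError(
            f"need >=2 sequences per class, got {len(lig)} ligases / {len(pro)} proteases"
        )
    if max_components is None:
        max_components = min(10, space.n_components)
    m = min(max_components, space.n_components)
    raw = []
    for c in range(m):
        x, y = space.scores[lig, c], space.scores[pro, c]
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        raw.append((float(res.statistic), float(res.pvalue)))
    pvals = np.array([p for _, p in raw])
    if correction == "holm":
        adjusted = _holm(pvals)
    else:
        adjusted = pvals.copy()
    return [
        ComponentSeparation(c, raw[c][0], raw[c][1], float(adjusted[c]),
                            bool(adjusted[c] < alpha))
        for c in range(m)
    ]


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass(frozen=True)
class ProfilePosition:
    column: int  # 0-based alignment column
    ref_number: int | None  # 1-based reference numbering, if mapped
    weight: float  # aggregate |loading| over selected components
    ideal: str  # ideal ligase residue, or '-' for deletion


@dataclass(frozen=True)
class LigaseProfile:
    """Ranked ligase-predictive alignment positions with ideal residues."""

    positions: tuple[ProfilePosition, ...]
    threshold: float = 0.25
    provenance: dict | None = None

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise SequenceSpaceError("threshold outside (0, 1]")
        cols = [p.column for p in self.positions]
        if len(set(cols)) != len(cols):
            raise SequenceSpaceError("duplicate profile positions")
        weights = [p.weight for p in self.positions]
        if any(a < b for a, b in zip(weights, weights[1:])):
            raise SequenceSpaceError("positions must be sorted by descending weight")

    @property
    def size(self) -> int:
        return len(self.positions)

    def to_json(self, path=None) -> str:
        payload = {
            "positions": [asdict(p) for p in self.positions],
            "size": self.size,
            "threshold": self.threshold,
            "provenance": self.provenance or {},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "LigaseProfile":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        positions = tuple(
            ProfilePosition(p["column"], p.get("ref_number"), p["weight"], p["ideal"])
            for p in payload["positions"]
        )
        return cls(positions, payload.get("threshold", 0.25),
                   payload.get("provenance") or None)


def column_weights(space: SequenceSpace, selected: list[int]) -> np.ndarray:
    """Aggregate per-column weight: sum of |loadings| over the selected
    components and the five properties of each column."""
    if not selected:
        raise SequenceSpaceError("no components selected")
    sub = np.abs(space.loadings[:, selected]).sum(axis=1)
    return sub.reshape(space.n_columns, N_PROPERTIES).sum(axis=1)


_RESIDUE_VECTORS: dict[str, np.ndarray] | None = None


def _residue_vectors() -> dict[str, np.ndarray]:
    """Min-max normalised 4-property vector per residue (for tie-breaks)."""
    global _RESIDUE_VECTORS
    if _RESIDUE_VECTORS is None:
        table = default_property_table()
        mat = np.array(
            [[table[p][aa] for p in PHYSICAL] for aa in AMINO_ACIDS], dtype=float
        )
        lo, hi = mat.min(axis=0), mat.max(axis=0)
        mat = (mat - lo) / np.where(hi > lo, hi - lo, 1.0)
        _RESIDUE_VECTORS = {aa: mat[i] for i, aa in enumerate(AMINO_ACIDS)}
    return _RESIDUE_VECTORS


def _ideal_residue(msa: Msa, column: int) -> str:
    """Modal residue among labelled ligases at a column.

    Gaps count as a state (returned as ``-``).  Ties are broken by the
    candidate whose normalised property vector lies nearest the mean
    vector of the ligase residues observed at the column (a gap candidate
    is placed at the column's all-sequence mean), then alphabetically.
    """
    lig_ids = msa.class_ids("ligase")
    if not lig_ids:
        raise SequenceSpaceError("no labelled ligases to derive ideal residues from")
    counts: dict[str, int] = {}
    for rid in lig_ids:
        ch = msa[rid][column]
        counts[ch] = counts.get(ch, 0) + 1
    top = max(counts.values())
    tied = sorted(ch for ch, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    vectors = _residue_vectors()
    lig_vecs = [vectors[msa[r][column]] for r in lig_ids if msa[r][column] in vectors]
    target = np.mean(lig_vecs, axis=0) if lig_vecs else None
    col_vecs = [vectors[s[column]] for _, s in msa.records if s[column] in vectors]
    col_mean = np.mean(col_vecs, axis=0) if col_vecs else None

    def distance(ch: str) -> float:
        if target is None:
            return 0.0
        vec = vectors.get(ch, col_mean if col_mean is not None else target)
        return float(np.linalg.norm(vec - target))

    return min(tied, key=lambda ch: (distance(ch), ch))


def extract_profile(
    space: SequenceSpace,
    selected: list[int] | list[ComponentSeparation],
    msa: Msa,
    k: int = 16,
    colmap: ColumnMap | None = None,
    threshold: float = 0.25,
) -> LigaseProfile:
    """Build the ligase profile from the top-weighted alignment columns.

    ``selected`` may be component indices or the output of
    :func:`rank_components` (its selected entries are used).  Ties at the
    k-th weight are broken toward the lower alignment column.
    """
    if selected and isinstance(selected[0], ComponentSeparation):
        selected = [c.component_index for c in selected if c.selected]
    if not selected:
        raise SequenceSpaceError("no components selected")
    if k > space.n_columns:
        raise SequenceSpaceError(f"k={k} exceeds {space.n_columns} columns")
    weights = column_weights(space, list(selected))
    order = sorted(range(space.n_columns), key=lambda c: (-weights[c], c))[:k]
    positions = tuple(
        ProfilePosition(
            column=c,
            ref_number=(colmap.col_to_ref.get(c) if colmap is not None else None),
            weight=float(weights[c]),
            ideal=_ideal_residue(msa, c),
        )
        for c in order
    )
    return LigaseProfile(positions, threshold=threshold,
                         provenance={"components": list(map(int, selected))})


@dataclass(frozen=True)
class MatchResult:
    """Ideal-residue match score and ligase/protease call for one sequence."""

    id: str
    n_match: int
    size: int
    predicted_class: str

    @property
    def score(self) -> float:
        return self.n_match / self.size


def match_score(sequence: str, profile: LigaseProfile, seq_id: str = "") -> MatchResult:
    """Fraction of profile positions carrying the ideal ligase residue.

    A deletion (gap) matches an ideal deletion; all non-profile positions
    are ignored.  The call is ligase iff score >= threshold (closed bound).
    """
    for pos in profile.positions:
        if pos.column >= len(sequence):
            raise SequenceSpaceError(
                f"profile column {pos.column} beyond sequence length {len(sequence)}"
            )
    n_match = sum(1 for p in profile.positions if sequence[p.column] == p.ideal)
    predicted = "ligase" if n_match / profile.size >= profile.threshold else "protease"
    return MatchResult(seq_id, n_match, profile.size, predicted)


def score_msa(msa: Msa, profile: LigaseProfile) -> list[MatchResult]:
    return [match_score(seq, profile, rid) for rid, seq in msa.records]


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion counts with ligase as the positive class.

    Two specificity variants are reported: ``specificity_standard`` is the
    usual TN/(TN+FP); ``specificity_printed`` is TN/(TP+FN), the formula
    printed in the source study's methods, reproduced verbatim and clearly
    labelled (it can exceed 1).
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def accuracy(self) -> float:
        return (self.TP + self.TN) / self.n

    @property
    def sensitivity(self) -> float:
        return self.TP / (self.TP + self.FN)

    @property
    def specificity_standard(self) -> float:
        return self.TN / (self.TN + self.FP)

    @property
    def specificity_printed(self) -> float:
        return self.TN / (self.TP + self.FN)

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "n": self.n,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity_standard": self.specificity_standard,
            "specificity_printed": self.specificity_printed,
        }


def evaluate(predictions: list[MatchResult], truth: dict[str, str]) -> ClassificationMetrics:
    """Confusion metrics over the labelled sequences (unknowns excluded)."""
    labelled = {rid: cls for rid, cls in truth.items() if cls in ("ligase", "protease")}
    if not labelled:
        raise SequenceSpaceError("no labelled ids to evaluate")
    by_id = {p.id: p for p in predictions}
    missing = set(labelled) - set(by_id)
    if missing:
        raise SequenceSpaceError(f"no prediction for labelled ids {sorted(missing)}")
    tp = fp = tn = fn = 0
    for rid, cls in labelled.items():
        pred = by_id[rid].predicted_class
        if cls == "ligase":
            tp += pred == "ligase"
            fn += pred == "protease"
        else:
            tn += pred == "protease"
            fp += pred == "ligase"
    return ClassificationMetrics(tp, fp, tn, fn)
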