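"""Model-object facade over the sequence-space pipeline.

:class:`AepSequenceSpace` bundles the encoding + PCA + component-selection
+ profile-extraction pipeline behind a familiar fit/results interface: the
model is constructed from a labelled alignment, ``fit()`` returns an
:class:`AepSequenceSpaceResults` holding the fitted space, the per-component
separation tests, the ligase profile, the match scores of the training
sequences and the confusion metrics over the labelled set, with a
``summary()`` table and a ``predict()`` method for new alignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .msa import ColumnMap, Msa, reference_numbering
from .properties import (
    EncodedMatrix,
    ResiduePropertyTable,
    default_property_table,
    encode,
    normalize_and_impute,
)
from .sequence_space import (
    ClassificationMetrics,
    ComponentSeparation,
    LigaseProfile,
    MatchResult,
    SequenceSpace,
    SequenceSpaceError,
    evaluate,
    extract_profile,
    fit_sequence_space,
    rank_components,
    score_msa,
)


class AepSequenceSpace:
    """Biophysical sequence-space model of ligase- vs protease-type AEPs.

    Parameters
    ----------
    msa : Msa
        Labelled alignment (>=2 ligases and >=2 proteases required to fit).
    property_table : ResiduePropertyTable, optional
        Residue descriptor scales; defaults to the packaged table.
    normalization : {"minmax", "zscore"}
        Per-property normalisation applied before PCA.
    ref_id : str, optional
        Reference sequence for residue numbering in reports (e.g. the
        OaAEP1_b row, so positions print as Cys247-style numbers).
    ref_offset : int
        Residue number of the reference's first aligned residue.
    """

    def __init__(
        self,
        msa: Msa,
        property_table: ResiduePropertyTable | None = None,
        normalization: str = "minmax",
        ref_id: str | None = None,
        ref_offset: int = 1,
    ):
        self.msa = msa
        self.property_table = property_table or default_property_table()
        self.normalization = normalization
        self.colmap: ColumnMap | None = (
            reference_numbering(msa, ref_id, ref_offset) if ref_id else None
        )
        raw = encode(msa, self.property_table)
        self.encoded: EncodedMatrix = normalize_and_impute(raw, normalization)

    @classmethod
    def from_msa(cls, msa: Msa, **kwargs) -> "AepSequenceSpace":
        return cls(msa, **kwargs)

    def fit(
        self,
        alpha: float = 0.05,
        k: int = 16,
        threshold: float = 0.25,
        max_components: int | None = None,
        correction: str = "holm",
    ) -> "AepSequenceSpaceResults":
        """Fit the space, select separating components, extract the profile
        and score the training alignment."""
        space = fit_sequence_space(self.encoded)
        separations = rank_components(
            space, self.msa.labels, alpha=alpha,
            max_components=max_components, correction=correction,
        )
        selected = [c.component_index for c in separations if c.selected]
        profile = None
        predictions: list[MatchResult] = []
        metrics = None
        if selected:
            profile = extract_profile(
                space, selected, self.msa, k=k, colmap=self.colmap, threshold=threshold
            )
            predictions = score_msa(self.msa, profile)
            if self.msa.labels:
                metrics = evaluate(predictions, self.msa.labels)
        return AepSequenceSpaceResults(
            model=self, space=space, separations=separations,
            profile=profile, predictions=predictions, metrics=metrics,
        )


@dataclass
class AepSequenceSpaceResults:
    """Fit results: space, separations, profile, scores and metrics."""

    model: AepSequenceSpace
    space: SequenceSpace
    separations: list[ComponentSeparation]
    profile: LigaseProfile | None
    predictions: list[MatchResult]
    metrics: ClassificationMetrics | None

    @property
    def selected_components(self) -> list[int]:
        return [c.component_index for c in self.separations if c.selected]

    def separations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": [c.component_index + 1 for c in self.separations],
                "U": [c.statistic for c in self.separations],
                "p_value": [c.p_value for c in self.separations],
                "p_adjusted": [c.p_adjusted for c in self.separations],
                "explained_variance": [
                    float(self.space.explained_variance[c.component_index])
                    for c in self.separations
                ],
                "selected": [c.selected for c in self.separations],
            }
        )

    def profile_frame(self) -> pd.DataFrame:
        if self.profile is None:
            raise SequenceSpaceError("no profile: no component separated the classes")
        return pd.DataFrame(
            {
                "column": [p.column for p in self.profile.positions],
                "ref_number": [p.ref_number for p in self.profile.positions],
                "weight": [p.weight for p in self.profile.positions],
                "ideal": [p.ideal for p in self.profile.positions],
            }
        )

    def scores_frame(self) -> pd.DataFrame:
        labels = self.model.msa.labels
        return pd.DataFrame(
            {
                "id": [p.id for p in self.predictions],
                "n_match": [p.n_match for p in self.predictions],
                "score": [p.score for p in self.predictions],
                "predicted_class": [p.predicted_class for p in self.predictions],
                "label": [labels.get(p.id, "unknown") for p in self.predictions],
            }
        )

    def coordinates_frame(self, components: list[int] | None = None) -> pd.DataFrame:
        """Per-sequence coordinates on selected (or given) components, for
        plotting."""
        comps = components if components is not None else (self.selected_components or [0, 1])
        data = {"id": list(self.space.ids)}
        for c in comps:
            data[f"PC{c + 1}"] = self.space.scores[:, c]
        data["label"] = [self.model.msa.label_of(r) for r in self.space.ids]
        return pd.DataFrame(data)

    def predict(self, msa: Msa) -> list[MatchResult]:
        """Score a new alignment (same column space) against the profile."""
        if self.profile is None:
            raise SequenceSpaceError("no profile to predict with")
        if msa.n_columns != self.model.msa.n_columns:
            raise SequenceSpaceError(
                "alignment width differs from the fitted alignment"
            )
        return score_msa(msa, self.profile)

    def plot_space(self, components: tuple[int, int] | None = None, ax=None):
        """Scatter of sequences on two components, coloured by class."""
        import matplotlib.pyplot as plt

        sel = self.selected_components
        cx, cy = components if components else (tuple(sel[:2]) if len(sel) >= 2 else (0, 1))
        if ax is None:
            _, ax = plt.subplots()
        colors = {"ligase": "red", "protease": "blue", "unknown": "0.7"}
        for cls in ("unknown", "protease", "ligase"):
            idx = [i for i, r in enumerate(self.space.ids)
                   if self.model.msa.label_of(r) == cls]
            if idx:
                ax.scatter(self.space.scores[idx, cx], self.space.scores[idx, cy],
                           c=colors[cls], label=cls, s=12)
        ax.set_xlabel(f"PC{cx + 1}")
        ax.set_ylabel(f"PC{cy + 1}")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable fit summary."""
        msa = self.model.msa
        n_lig = len(msa.class_ids("ligase"))
        n_pro = len(msa.class_ids("protease"))
        lines = [
            "AEP biophysical sequence-space model",
            "=" * 52,
            f"sequences: {len(msa)} ({n_lig} ligase, {n_pro} protease, "
            f"{len(msa) - n_lig - n_pro} unknown); columns: {msa.n_columns}",
            f"normalization: {self.model.normalization}; "
            f"components tested: {len(self.separations)}",
            "",
            "component separation (exact rank-sum, ligase vs protease)",
            self.separations_frame().to_string(index=False,
                                               float_format=lambda v: f"{v:.3g}"),
        ]
        if self.profile is not None:
            lines += [
                "",
                f"ligase profile: {self.profile.size} positions, "
                f"match threshold >= {self.profile.threshold:.0%}",
                self.profile_frame().to_string(index=False,
                                               float_format=lambda v: f"{v:.3f}"),
            ]
        if self.metrics is not None:
            m = self.metrics
            lines += [
                "",
                f"labelled-set classification (n={m.n}): "
                f"TP={m.TP} FP={m.FP} TN={m.TN} FN={m.FN}",
                f"accuracy={m.accuracy:.3f}  sensitivity={m.sensitivity:.3f}  "
                f"specificity={m.specificity_standard:.3f} "
                f"(printed-formula specificity={m.specificity_printed:.3f})",
            ]
        return "\n".join(lines)
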