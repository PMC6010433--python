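"""End-to-end workflows with reproducible artifacts.

Two pipelines mirror the two halves of the analysis: the sequence-space
fit/score workflow (encode -> PCA -> component selection -> profile ->
match scores -> metrics) and the MLA screen workflow.  Both write their
artifacts plus a manifest (configuration, package version, input
checksums) so a run can be re-executed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .mla import MlaRegion, screen, write_report_tsv
from .model import AepSequenceSpace
from .msa import Msa, attach_labels, read_labels, read_msa, reference_numbering

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration shared by the workflows.

    Defaults follow the published analysis constants: a 16-position
    profile, >=25% match threshold, GRAVY cutoff 0.0, MLA span 294-301 and
    Gatekeeper residue 247 in reference numbering.
    """

    msa_path: str = ""
    labels_path: str | None = None
    out_dir: str = "."
    normalization: str = "minmax"
    alpha: float = 0.05
    k: int = 16
    threshold: float = 0.25
    correction: str = "holm"
    max_components: int | None = None
    ref_id: str | None = None
    ref_offset: int = 1
    mla_start: int = 294
    mla_end: int = 301
    gatekeeper_ref: int = 247
    delta: int = 3
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: RunConfig, out: Path, inputs: list[str]) -> None:
    manifest = {
        "config": config.as_dict(),
        "version": __version__,
        "inputs": {p: _sha256(p) for p in inputs if p and Path(p).exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _load_msa(config: RunConfig) -> Msa:
    msa = read_msa(config.msa_path)
    if config.labels_path:
        try:
            msa = attach_labels(msa, read_labels(config.labels_path))
        except Exception as exc:
            raise RuntimeError(f"stage attach_labels failed: {exc}") from exc
    return msa


def run_sequence_space_workflow(config: RunConfig) -> dict:
    """Fit the sequence space and write profile/scores/metrics artifacts.

    Returns a dict of artifact paths plus the in-memory results object.
    Identical config + inputs produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    msa = _load_msa(config)
    model = AepSequenceSpace(
        msa, normalization=config.normalization,
        ref_id=config.ref_id, ref_offset=config.ref_offset,
    )
    results = model.fit(
        alpha=config.alpha, k=config.k, threshold=config.threshold,
        max_components=config.max_components, correction=config.correction,
    )
    artifacts = {"results": results}
    results.separations_frame().to_csv(out / "components.tsv", sep="\t", index=False)
    artifacts["components"] = str(out / "components.tsv")
    if results.profile is not None:
        results.profile.to_json(out / "profile.json")
        results.scores_frame().to_csv(out / "scores.tsv", sep="\t", index=False)
        results.coordinates_frame().to_csv(out / "coordinates.tsv", sep="\t", index=False)
        artifacts.update(
            profile=str(out / "profile.json"),
            scores=str(out / "scores.tsv"),
            coordinates=str(out / "coordinates.tsv"),
        )
    if results.metrics is not None:
        (out / "metrics.json").write_text(
            json.dumps(results.metrics.as_dict(), indent=2, sort_keys=True) + "\n"
        )
        artifacts["metrics"] = str(out / "metrics.json")
    (out / "summary.txt").write_text(results.summary() + "\n")
    artifacts["summary"] = str(out / "summary.txt")
    _write_manifest(config, out, [config.msa_path, config.labels_path or ""])
    return artifacts


def run_screen_workflow(config: RunConfig, profile=None) -> dict:
    """Run the MLA screen over an alignment and write the report.

    Candidates are sorted first (by candidate flag, then match score when a
    profile is given, then GRAVY).
    """
    if not config.ref_id:
        raise RuntimeError("stage reference_numbering failed: ref_id required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    msa = _load_msa(config)
    colmap = reference_numbering(msa, config.ref_id, config.ref_offset)
    region = MlaRegion.from_reference(msa, colmap, config.mla_start, config.mla_end)
    reports = screen(
        msa, colmap, region, profile=profile,
        delta=config.delta, gatekeeper_ref=config.gatekeeper_ref,
    )
    reports.sort(
        key=lambda r: (
            r.candidate,
            r.match_score if r.match_score is not None else -1.0,
            r.gravy if r.gravy is not None else float("-inf"),
        ),
        reverse=True,
    )
    write_report_tsv(reports, out / "mla_report.tsv")
    (out / "mla_report.json").write_text(
        json.dumps([r.as_dict() for r in reports], indent=2) + "\n"
    )
    _write_manifest(config, out, [config.msa_path, config.labels_path or ""])
    return {
        "reports": reports,
        "tsv": str(out / "mla_report.tsv"),
        "json": str(out / "mla_report.json"),
    }
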