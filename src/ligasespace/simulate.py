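"""Synthetic AEP-like alignments with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, without any real-data dependence:

* background columns whose residue frequencies are drawn per column from a
  Dirichlet (the concentration parameter tunes conservation);
* a small set of class-diagnostic columns where ligase and protease rows
  carry property-contrasting residues with a configurable fidelity;
* an MLA-like column span where ligase rows are truncated (gapped) or
  hydrophobic and protease rows are hydrophilic and extended, optionally
  carrying a planted N-X-S/T sequon;
* sparse random gaps outside the planted structure.

Every generated alignment comes with a :class:`SyntheticTruth` recording
exactly what was planted, so profile recovery, classifier operating
characteristics and the MLA screen can all be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np

from .msa import AMINO_ACIDS, GAP, Msa
from . import mla as mla_mod

#: residue pairs with strong biophysical contrast (charge and/or
#: hydropathy), so the property encoding - not raw identity - carries the
#: class signal at diagnostic columns.
CONTRAST_PAIRS = [
    ("I", "D"), ("L", "K"), ("V", "E"), ("F", "R"), ("C", "N"),
    ("M", "Q"), ("A", "H"), ("W", "S"), ("I", "K"), ("L", "E"),
]

HYDROPHOBIC = "AILVFMC"  # Kyte-Doolittle > 0
HYDROPHILIC = "DEKQRGH"  # strongly negative Kyte-Doolittle, no N/S/T
# N, S, T are excluded from the hydrophilic pool so that sequons appear
# only where the generator plants them.


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic alignment generator.

    Defaults emulate a modestly sized study: 10 ligase-type, 30
    protease-type and 60 unannotated sequences over 120 alignment columns,
    16 diagnostic columns carried with 0.9 fidelity, a 12-column MLA-like
    span with 5-column ligase truncations, and half of the protease rows
    carrying a planted sequon.
    """

    n_ligase: int = 10
    n_protease: int = 30
    n_unknown: int = 60
    n_columns: int = 120
    n_diagnostic: int = 16
    signal_fidelity: float = 0.9
    background_entropy: float = 0.5  # Dirichlet concentration per residue
    mla_span: tuple[int, int] = (104, 115)  # inclusive columns
    truncation_length: int = 5
    p_truncation_ligase: float = 0.7
    p_sequon_protease: float = 0.5
    gap_rate: float = 0.02
    #: "class" links the MLA span to the class (truncated/hydrophobic
    #: ligases vs hydrophilic extended proteases); "neutral" gives every
    #: row a class-independent hydrophilic loop, isolating the diagnostic
    #: columns as the only class signal (for recovery and null studies).
    mla_mode: str = "class"
    seed: int = 0

    def __post_init__(self):
        for name in ("signal_fidelity", "p_truncation_ligase", "p_sequon_protease", "gap_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.n_diagnostic >= self.n_columns:
            raise ConfigError("n_diagnostic must be < n_columns")
        lo, hi = self.mla_span
        if not (0 <= lo <= hi < self.n_columns):
            raise ConfigError("mla_span outside columns")
        if hi - lo + 1 < self.truncation_length + 1:
            raise ConfigError("mla_span shorter than truncation")
        if hi - lo + 1 < 3:
            raise ConfigError("mla_span too short for a sequon")
        if self.n_ligase < 2 or self.n_protease < 2:
            raise ConfigError("need >=2 sequences per labelled class")
        if self.mla_mode not in ("class", "neutral"):
            raise ConfigError(f"unknown mla_mode {self.mla_mode!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """What the generator planted, for recovery testing."""

    diagnostic_columns: tuple[int, ...]
    ligase_residues: dict[int, str]
    protease_residues: dict[int, str]
    classes: dict[str, str]
    mla_types: dict[str, str]  # truncated / hydrophobic / hydrophilic_extended
    sequon_positions: dict[str, tuple[int, ...]]  # 1-based within segment
    seed: int

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["diagnostic_columns"] = list(self.diagnostic_columns)
        payload["sequon_positions"] = {k: list(v) for k, v in self.sequon_positions.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _background_profiles(rng, n_columns: int, concentration: float) -> np.ndarray:
    return rng.dirichlet([concentration] * len(AMINO_ACIDS), size=n_columns)


def _sample_residue(rng, profile: np.ndarray) -> str:
    return AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=profile)]


def generate(config: SyntheticConfig | None = None, **overrides) -> tuple[Msa, SyntheticTruth]:
    """Generate a labelled synthetic alignment and its ground truth.

    Deterministic given ``config.seed``: the same configuration always
    yields byte-identical sequences.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ConfigError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mla_span
    span_cols = list(range(lo, hi + 1))
    span_len = len(span_cols)

    profiles = _background_profiles(rng, config.n_columns, config.background_entropy)
    candidates = [c for c in range(config.n_columns) if c not in span_cols]
    diag_cols = tuple(sorted(rng.choice(candidates, config.n_diagnostic, replace=False).tolist()))
    lig_res: dict[int, str] = {}
    pro_res: dict[int, str] = {}
    for i, c in enumerate(diag_cols):
        a, b = CONTRAST_PAIRS[i % len(CONTRAST_PAIRS)]
        lig_res[c], pro_res[c] = a, b

    ids_classes = (
        [(f"LIG{i:04d}", "ligase") for i in range(config.n_ligase)]
        + [(f"PRO{i:04d}", "protease") for i in range(config.n_protease)]
        + [(f"UNK{i:04d}", "unknown") for i in range(config.n_unknown)]
    )
    records: list[tuple[str, str]] = []
    classes: dict[str, str] = {}
    mla_types: dict[str, str] = {}
    sequons: dict[str, tuple[int, ...]] = {}

    for rid, cls in ids_classes:
        row = [_sample_residue(rng, profiles[c]) for c in range(config.n_columns)]
        # diagnostic columns
        for c in diag_cols:
            if cls == "ligase":
                if rng.random() < config.signal_fidelity:
                    row[c] = lig_res[c]
            elif cls == "protease":
                if rng.random() < config.signal_fidelity:
                    row[c] = pro_res[c]
            # unknowns keep the background draw
        # MLA span
        if config.mla_mode == "neutral":
            mla_types[rid] = "hydrophilic_extended"
            for c in span_cols:
                row[c] = rng.choice(list(HYDROPHILIC))
            sequons[rid] = ()
        elif cls == "ligase" and rng.random() < config.p_truncation_ligase:
            mla_types[rid] = "truncated"
            kept = span_len - config.truncation_length
            segment = [rng.choice(list(HYDROPHOBIC + HYDROPHILIC)) for _ in range(kept)]
            filled = segment + [GAP] * config.truncation_length
            for c, ch in zip(span_cols, filled):
                row[c] = ch
            sequons[rid] = ()
        elif cls == "ligase":
            mla_types[rid] = "hydrophobic"
            while True:
                seg = [rng.choice(list(HYDROPHOBIC)) for _ in range(span_len)]
                if mla_mod.gravy("".join(seg)) > 0:
                    break
            for c, ch in zip(span_cols, seg):
                row[c] = ch
            sequons[rid] = ()
        else:  # protease-type and unknown rows: hydrophilic, extended
            mla_types[rid] = "hydrophilic_extended"
            seg = [rng.choice(list(HYDROPHILIC)) for _ in range(span_len)]
            planted: tuple[int, ...] = ()
            if cls == "protease" and rng.random() < config.p_sequon_protease:
                pos = int(rng.integers(0, span_len - 2))
                x = rng.choice([ch for ch in HYDROPHILIC if ch != "P"])
                seg[pos : pos + 3] = ["N", x, rng.choice(["S", "T"])]
                planted = (pos + 1,)
            for c, ch in zip(span_cols, seg):
                row[c] = ch
            sequons[rid] = planted
        # sparse random gaps outside planted structure
        if config.gap_rate > 0:
            for c in range(config.n_columns):
                if c in span_cols or c in lig_res:
                    continue
                if rng.random() < config.gap_rate:
                    row[c] = GAP
        records.append((rid, "".join(row)))
        classes[rid] = cls

    labels = {rid: cls for rid, cls in classes.items() if cls != "unknown"}
    msa = Msa(tuple(records), labels)
    truth = SyntheticTruth(
        diagnostic_columns=diag_cols,
        ligase_residues=lig_res,
        protease_residues=pro_res,
        classes=classes,
        mla_types=mla_types,
        sequon_positions=sequons,
        seed=config.seed,
    )
    return msa, truth


class IntegrityError(AssertionError):
    pass


def truth_checks(msa: Msa, truth: SyntheticTruth, config: SyntheticConfig) -> dict:
    """Verify planted properties hold and summarise realized frequencies.

    Checks that hydrophobic MLA rows have GRAVY > 0, that every planted
    sequon is detectable by :func:`ligasespace.mla.find_sequons`, and that
    truncated rows are shorter than extended ones; returns realized
    per-column class-residue frequencies for power analysis.
    """
    lo, hi = config.mla_span
    seqs = dict(msa.records)
    fidelity: dict[int, dict[str, float]] = {}
    for c in truth.diagnostic_columns:
        for cls, res in (("ligase", truth.ligase_residues[c]),
                         ("protease", truth.protease_residues[c])):
            rows = [r for r, k in truth.classes.items() if k == cls]
            hit = sum(seqs[r][c] == res for r in rows)
            fidelity.setdefault(c, {})[cls] = hit / len(rows)
    for rid, mtype in truth.mla_types.items():
        segment = seqs[rid][lo : hi + 1].replace(GAP, "")
        if mtype == "hydrophobic" and mla_mod.gravy(segment) <= 0:
            raise IntegrityError(f"{rid}: hydrophobic MLA with GRAVY <= 0")
        if mtype == "truncated" and len(segment) != (hi - lo + 1) - config.truncation_length:
            raise IntegrityError(f"{rid}: truncation length mismatch")
        found = tuple(mla_mod.find_sequons(segment))
        planted = truth.sequon_positions[rid]
        if set(planted) - set(found):
            raise IntegrityError(f"{rid}: planted sequon {planted} not found ({found})")
    return {
        "realized_fidelity": fidelity,
        "mean_fidelity_ligase": float(np.mean(
            [f["ligase"] for f in fidelity.values()])) if fidelity else float("nan"),
        "mean_fidelity_protease": float(np.mean(
            [f["protease"] for f in fidelity.values()])) if fidelity else float("nan"),
    }
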