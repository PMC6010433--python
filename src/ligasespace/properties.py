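"""Biophysical-property encoding of a protein alignment.

Every alignment cell is described by five descriptors: side-chain (R-group)
mass, net charge at pH 7, Kyte-Doolittle hydropathy, TOP-IDP disorder
propensity, and a binary occupancy (residue present vs gap).  The four
physical descriptors are normalised within each property across the whole
matrix, and gap cells are imputed with the column mean of the normalised
observed values; occupancy is never imputed.  The resulting matrix of
``n_sequences x (n_columns * 5)`` features is the substrate for PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .msa import AMINO_ACIDS, GAP, AlphabetError, Msa

PROPERTIES = ("r_group_mass", "net_charge", "hydropathy", "top_idp", "occupancy")
PHYSICAL = PROPERTIES[:4]
N_PROPERTIES = len(PROPERTIES)


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class ResiduePropertyTable:
    """Per-amino-acid descriptor values.

    ``values[property][aa]`` gives the raw descriptor for one of the 20
    canonical residues.  Occupancy is implicit (1 for any residue, 0 for a
    gap) and is not stored here.
    """

    values: dict[str, dict[str, float]]

    def __post_init__(self):
        for prop in PHYSICAL:
            if prop not in self.values:
                raise EncodingError(f"missing property {prop!r}")
            covered = set(self.values[prop])
            if covered != set(AMINO_ACIDS):
                raise EncodingError(
                    f"property {prop!r} must cover exactly the 20 amino acids"
                )

    def __getitem__(self, prop: str) -> dict[str, float]:
        return self.values[prop]

    def with_his_charge(self, charge: float) -> "ResiduePropertyTable":
        """Return a copy with the histidine charge convention changed."""
        vals = {p: dict(v) for p, v in self.values.items()}
        vals["net_charge"]["H"] = charge
        return ResiduePropertyTable(vals)


def default_property_table() -> ResiduePropertyTable:
    """Load the packaged descriptor table.

    The table carries the published Kyte-Doolittle hydropathy and TOP-IDP
    disorder scales, average side-chain masses and formal charges at pH 7
    (His at +0.1 by default for partial imidazole protonation at the mildly
    acidic pH of the plant vacuole where AEPs mature).
    """
    text = (
        resources.files("ligasespace").joinpath("data/residue_properties.tsv")
    ).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    values: dict[str, dict[str, float]] = {p: {} for p in header[1:]}
    for ln in lines[1:]:
        parts = ln.split("\t")
        aa = parts[0]
        for prop, raw in zip(header[1:], parts[1:]):
            values[prop][aa] = float(raw)
    return ResiduePropertyTable(values)


@dataclass
class EncodedMatrix:
    """The numericised alignment.

    Feature ``j = column * 5 + property_index`` with properties ordered as
    :data:`PROPERTIES`.  Missing cells (gaps / ``X`` on physical
    properties) are NaN until :func:`normalize_and_impute` runs.
    """

    values: np.ndarray  # n_sequences x (n_columns * 5)
    ids: list[str]
    n_columns: int
    normalization_record: dict[str, tuple[float, float]] = field(default_factory=dict)
    imputation_record: dict[int, int] = field(default_factory=dict)

    @property
    def n_sequences(self) -> int:
        return self.values.shape[0]

    def feature_index(self, feature: int) -> tuple[int, str]:
        """Map a flat feature index to ``(alignment column, property)``."""
        return feature // N_PROPERTIES, PROPERTIES[feature % N_PROPERTIES]

    def feature_of(self, column: int, prop: str) -> int:
        return column * N_PROPERTIES + PROPERTIES.index(prop)

    def property_slice(self, prop: str) -> np.ndarray:
        """View of all columns of one property (n_sequences x n_columns)."""
        return self.values[:, PROPERTIES.index(prop) :: N_PROPERTIES]

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def occupancy_mask(self) -> np.ndarray:
        """Boolean residue-present mask, n_sequences x n_columns."""
        return self.property_slice("occupancy") > 0.5


def encode(msa: Msa, table: ResiduePropertyTable | None = None) -> EncodedMatrix:
    """Numericise an alignment into the raw (unnormalised) property matrix.

    Gaps are missing (NaN) on the four physical properties and 0 on
    occupancy; ``X`` is present (occupancy 1) but missing on the physical
    properties.
    """
    if table is None:
        table = default_property_table()
    n_seq, n_col = len(msa), msa.n_columns
    values = np.full((n_seq, n_col * N_PROPERTIES), np.nan)
    prop_vectors = {
        prop: np.array([table[prop][aa] for aa in AMINO_ACIDS]) for prop in PHYSICAL
    }
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for s, (rid, seq) in enumerate(msa.records):
        for c, ch in enumerate(seq):
            base = c * N_PROPERTIES
            if ch == GAP:
                values[s, base + 4] = 0.0
            elif ch == "X":
                values[s, base + 4] = 1.0
            elif ch in aa_index:
                k = aa_index[ch]
                for p, prop in enumerate(PHYSICAL):
                    values[s, base + p] = prop_vectors[prop][k]
                values[s, base + 4] = 1.0
            else:
                raise AlphabetError(f"residue {ch!r} in {rid!r} not in property table")
    return EncodedMatrix(values, list(msa.ids), n_col)


def normalize_and_impute(raw: EncodedMatrix, method: str = "minmax") -> EncodedMatrix:
    """Normalise each physical property, then impute gaps with column means.

    Normalisation pools all alignment columns of a property (min-max to
    [0, 1] by default, or z-score), which preserves between-column
    contrasts.  Each missing cell then receives the arithmetic mean of the
    normalised observed values in its own column; a column with no observed
    residue falls back to the property's global mean.  Occupancy is left
    untouched, so gaps stay exactly 0.
    """
    if raw.values.size == 0:
        raise EncodingError("empty matrix")
    if method not in ("minmax", "zscore"):
        raise EncodingError(f"unknown normalization {method!r}")
    out = raw.values.copy()
    norm_record: dict[str, tuple[float, float]] = {}
    imput_record: dict[int, int] = {}
    for p, prop in enumerate(PHYSICAL):
        sl = out[:, p::N_PROPERTIES]
        observed = sl[~np.isnan(sl)]
        if observed.size == 0:
            raise EncodingError(f"property {prop!r} has no observed values")
        if method == "minmax":
            lo, hi = float(observed.min()), float(observed.max())
            norm_record[prop] = (lo, hi)
            if hi == lo:
                warnings.warn(f"property {prop!r} constant; filling 0.5")
                sl[~np.isnan(sl)] = 0.5
            else:
                sl[:] = (sl - lo) / (hi - lo)
        else:
            mu, sd = float(observed.mean()), float(observed.std(ddof=0))
            norm_record[prop] = (mu, sd)
            if sd == 0:
                warnings.warn(f"property {prop!r} constant; filling 0.0")
                sl[~np.isnan(sl)] = 0.0
            else:
                sl[:] = (sl - mu) / sd
        global_mean = float(np.nanmean(sl))
        for c in range(raw.n_columns):
            col = sl[:, c]
            missing = np.isnan(col)
            if not missing.any():
                continue
            fill = float(col[~missing].mean()) if (~missing).any() else global_mean
            col[missing] = fill
            imput_record[raw.feature_of(c, prop)] = int(missing.sum())
    return EncodedMatrix(out, list(raw.ids), raw.n_columns, norm_record, imput_record)
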