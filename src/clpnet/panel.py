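"""Panel data container, CSV readers/writers, recoding and GHQ scoring.

A :class:`PanelDataset` holds ordinal responses as a dense
``(n_subjects, n_waves, n_items)`` float array with ``NaN`` marking
missing observations — missingness is never encoded by an in-range
sentinel. Auxiliary per-subject covariates (sex, ethnicity, age) travel
alongside for imputation and missingness modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schema import GHQ_ITEM_IDS, ItemSchema, default_schema

logger = logging.getLogger(__name__)

#: Caseness cutoff for the GHQ-12 sum score: scores strictly above this
#: value indicate probable mental distress.
GHQ_CASENESS_CUTOFF = 11

AUX_COLUMNS = ["sex", "ethnicity", "age"]


class PanelValidationError(ValueError):
    """A response violates its item's scale bounds or the panel layout."""


class PanelSchemaError(ValueError):
    """Declared columns or items are missing from an input file."""


@dataclass
class PanelDataset:
    """Subjects x waves x items ordinal panel with explicit missingness.

    Attributes
    ----------
    subjects
        Array of unique subject identifiers, one per row of ``responses``.
    waves
        Ordered wave labels.
    responses
        Float array of shape ``(n_subjects, n_waves, n_items)``; ``NaN``
        marks a missing response.
    schema
        One :class:`~clpnet.schema.ItemSchema` per item, in column order.
    aux
        Optional per-subject covariates (``sex``, ``ethnicity`` coded 0/1
        and ``age`` in years), indexed like ``subjects``.
    """

    subjects: np.ndarray
    waves: list[str]
    responses: np.ndarray
    schema: list[ItemSchema] = field(default_factory=default_schema)
    aux: pd.DataFrame | None = None
    #: bootstrap resamples carry duplicated subject ids on purpose
    unique_subjects: bool = True

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.responses = np.asarray(self.responses, dtype=float)
        self.waves = list(self.waves)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, w, p = self.responses.shape
        if n != len(self.subjects):
            raise PanelValidationError(
                f"{len(self.subjects)} subjects but {n} response rows"
            )
        if w != len(self.waves):
            raise PanelValidationError(f"{len(self.waves)} waves but {w} wave slabs")
        if p != len(self.schema):
            raise PanelValidationError(f"{len(self.schema)} items but {p} item columns")
        if len(set(self.waves)) != len(self.waves):
            raise PanelValidationError("wave labels must be unique")
        if self.unique_subjects and len(np.unique(self.subjects)) != n:
            raise PanelValidationError("subject identifiers must be unique")
        for k, item in enumerate(self.schema):
            col = self.responses[:, :, k]
            obs = col[~np.isnan(col)]
            bad = (obs < item.scale_min) | (obs > item.scale_max)
            if bad.any():
                i, j = np.argwhere(~np.isnan(col))[np.flatnonzero(bad)[0]]
                raise PanelValidationError(
                    f"response {col[i, j]!r} for item {item.item_id!r} out of "
                    f"[{item.scale_min}, {item.scale_max}] "
                    f"(subject {self.subjects[i]!r}, wave {self.waves[j]!r})"
                )
        if self.aux is not None and len(self.aux) != n:
            raise PanelValidationError("aux covariates must have one row per subject")

    # -- conveniences ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.responses.shape[0]

    @property
    def n_waves(self) -> int:
        return self.responses.shape[1]

    @property
    def n_items(self) -> int:
        return self.responses.shape[2]

    @property
    def item_ids(self) -> list[str]:
        return [s.item_id for s in self.schema]

    def wave_index(self, wave: str) -> int:
        try:
            return self.waves.index(wave)
        except ValueError:
            raise KeyError(f"unknown wave {wave!r}; have {self.waves}") from None

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item {item_id!r}") from None

    def wave_matrix(self, wave: str) -> np.ndarray:
        """``(n_subjects, n_items)`` response matrix for one wave (NaN = missing)."""
        return self.responses[:, self.wave_index(wave), :]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.responses)

    def copy(self) -> "PanelDataset":
        return replace(
            self,
            responses=self.responses.copy(),
            aux=None if self.aux is None else self.aux.copy(),
        )

    def subset(self, keep: np.ndarray) -> "PanelDataset":
        """New dataset restricted to the boolean/index mask *keep* over subjects."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return replace(
            self,
            subjects=self.subjects[idx],
            responses=self.responses[idx],
            aux=None if self.aux is None else self.aux.iloc[idx].reset_index(drop=True),
        )

    def subset_resample(self, idx: np.ndarray) -> "PanelDataset":
        """Row selection that may repeat subjects (bootstrap resampling).

        Original subject ids are kept on the duplicated rows so that
        hash-based CV fold assignment stays stable across resamples.
        """
        idx = np.asarray(idx)
        return replace(
            self,
            subjects=self.subjects[idx],
            responses=self.responses[idx],
            aux=None if self.aux is None else self.aux.iloc[idx].reset_index(drop=True),
            unique_subjects=False,
        )

    # -- tabular views ---------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        """Wide table: one row per subject, ``{item}__{wave}`` response columns."""
        data: dict[str, np.ndarray] = {"subject": self.subjects}
        if self.aux is not None:
            for c in self.aux.columns:
                data[c] = self.aux[c].to_numpy()
        for j, wave in enumerate(self.waves):
            for k, item in enumerate(self.schema):
                data[f"{item.item_id}__{wave}"] = self.responses[:, j, k]
        return pd.DataFrame(data)

    def to_long_frame(self) -> pd.DataFrame:
        """Long table with columns subject, wave, item, value (observed cells only)."""
        i, j, k = np.nonzero(~np.isnan(self.responses))
        return pd.DataFrame(
            {
                "subject": self.subjects[i],
                "wave": np.asarray(self.waves, dtype=object)[j],
                "item": np.asarray(self.item_ids, dtype=object)[k],
                "value": self.responses[i, j, k],
            }
        )


# ---------------------------------------------------------------------------
# IO


def _coerce_values(
    raw: pd.Series, na_codes: tuple[float, ...] | list[float]
) -> np.ndarray:
    vals = pd.to_numeric(raw, errors="coerce").astype(float).to_numpy()
    for code in na_codes:
        vals[vals == code] = np.nan
    return vals


def read_panel(
    path,
    schema: list[ItemSchema] | None = None,
    format_config: dict | None = None,
) -> PanelDataset:
    """Read a delimited panel file into a validated :class:`PanelDataset`.

    ``format_config`` keys (all optional):

    ``format``
        ``"wide"`` (default; ``{item}__{wave}`` columns, one row per
        subject) or ``"long"`` (``subject,wave,item,value`` rows).
    ``sep``
        Field delimiter, default ``","``.
    ``subject_col``, ``wave_col``, ``item_col``, ``value_col``
        Column-name overrides (long format).
    ``waves``
        Explicit ordered wave labels; inferred from the file otherwise.
    ``na_codes``
        Sentinel numeric codes (e.g. negative survey codes) mapped to
        missing. Any other unparseable or out-of-range value raises.
    ``aux_cols``
        Mapping from the auxiliary covariate names (``sex``, ``ethnicity``,
        ``age``) to file columns; defaults to same-named columns if present.
    """
    schema = schema if schema is not None else default_schema()
    cfg = dict(format_config or {})
    fmt = cfg.get("format", "wide")
    sep = cfg.get("sep", ",")
    na_codes = tuple(cfg.get("na_codes", ()))
    df = pd.read_csv(path, sep=sep)

    item_ids = [s.item_id for s in schema]
    if fmt == "long":
        sub_c = cfg.get("subject_col", "subject")
        wav_c = cfg.get("wave_col", "wave")
        itm_c = cfg.get("item_col", "item")
        val_c = cfg.get("value_col", "value")
        for c in (sub_c, wav_c, itm_c, val_c):
            if c not in df.columns:
                raise PanelSchemaError(f"declared column {c!r} not in file")
        waves = list(cfg.get("waves", pd.unique(df[wav_c]).tolist()))
        subjects = pd.unique(df[sub_c])
        sub_pos = {s: i for i, s in enumerate(subjects)}
        wav_pos = {w: i for i, w in enumerate(waves)}
        itm_pos = {it: i for i, it in enumerate(item_ids)}
        unknown = set(df[itm_c]) - set(item_ids)
        if unknown:
            raise PanelSchemaError(f"items not in schema: {sorted(unknown)!r}")
        responses = np.full((len(subjects), len(waves), len(item_ids)), np.nan)
        vals = _coerce_values(df[val_c], na_codes)
        ii = df[sub_c].map(sub_pos).to_numpy()
        jj = df[wav_c].map(wav_pos).to_numpy()
        kk = df[itm_c].map(itm_pos).to_numpy()
        dup = pd.DataFrame({"i": ii, "j": jj, "k": kk}).duplicated()
        if dup.any():
            raise PanelValidationError("duplicate (subject, wave, item) rows in file")
        responses[ii, jj, kk] = vals
        aux_source = df.drop_duplicates(sub_c).set_index(sub_c)
    elif fmt == "wide":
        sub_c = cfg.get("subject_col", "subject")
        if sub_c not in df.columns:
            raise PanelSchemaError(f"declared column {sub_c!r} not in file")
        waves = list(
            cfg.get(
                "waves",
                _infer_waves(df.columns, item_ids),
            )
        )
        subjects = df[sub_c].to_numpy()
        responses = np.full((len(subjects), len(waves), len(item_ids)), np.nan)
        for j, wave in enumerate(waves):
            for k, item_id in enumerate(item_ids):
                col = f"{item_id}__{wave}"
                if col not in df.columns:
                    raise PanelSchemaError(f"declared column {col!r} not in file")
                responses[:, j, k] = _coerce_values(df[col], na_codes)
        aux_source = df.set_index(sub_c)
    else:
        raise PanelSchemaError(f"unknown format {fmt!r}; expected 'wide' or 'long'")

    aux_cols = cfg.get("aux_cols", {c: c for c in AUX_COLUMNS if c in aux_source.columns})
    aux = None
    if aux_cols:
        missing = [c for c in aux_cols.values() if c not in aux_source.columns]
        if missing:
            raise PanelSchemaError(f"auxiliary columns not in file: {missing!r}")
        aux = pd.DataFrame(
            {name: aux_source.loc[subjects, col].to_numpy() for name, col in aux_cols.items()}
        )
    return PanelDataset(np.asarray(subjects), waves, responses, schema, aux)


def _infer_waves(columns, item_ids) -> list[str]:
    first = item_ids[0] + "__"
    waves = [c[len(first):] for c in columns if c.startswith(first)]
    if not waves:
        raise PanelSchemaError(
            f"no '{item_ids[0]}__<wave>' columns found; declare 'waves' explicitly"
        )
    return waves


def write_panel(data: PanelDataset, path, fmt: str = "wide") -> None:
    """Write a panel to CSV in wide (default) or long layout."""
    frame = data.to_wide_frame() if fmt == "wide" else data.to_long_frame()
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Recoding and scoring


def recode_items(data: PanelDataset) -> PanelDataset:
    """Reflect reverse-coded items so higher values mean poorer health.

    A flagged item's value ``x`` becomes ``scale_min + scale_max - x``;
    unflagged items pass through. Applying the operation twice restores
    the original dataset (reflection is an involution).
    """
    out = data.responses.copy()
    for k, item in enumerate(data.schema):
        if item.reverse_coded:
            out[:, :, k] = item.scale_min + item.scale_max - out[:, :, k]
    return replace(data, responses=out)


def ghq_sum_and_caseness(data: PanelDataset, wave: str) -> pd.DataFrame:
    """Per-subject GHQ-12 sum score and caseness flag at one wave.

    The sum spans the 12 GHQ items only (loneliness excluded); caseness is
    ``sum > 11``. A subject with any missing GHQ item at the wave gets a
    missing score and missing caseness — they are flagged, never dropped.
    """
    ghq_idx = [data.item_index(i) for i in GHQ_ITEM_IDS if i in data.item_ids]
    if len(ghq_idx) != 12:
        raise PanelValidationError(
            f"expected the 12 GHQ items in the schema, found {len(ghq_idx)}"
        )
    mat = data.wave_matrix(wave)[:, ghq_idx]
    complete = ~np.isnan(mat).any(axis=1)
    sums = np.where(complete, np.nansum(mat, axis=1), np.nan)
    case = pd.array(sums > GHQ_CASENESS_CUTOFF, dtype="boolean")
    case[~complete] = pd.NA
    return pd.DataFrame(
        {"subject": data.subjects, "ghq_sum": sums, "caseness": case}
    )
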