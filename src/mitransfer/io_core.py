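"""Input tables, depth filtering and dyad construction.

The pipeline is driven by three tables: an ASV count table (samples x
amplicon sequence variants), a sample metadata table (who the sample came
from, which body compartment, when, and how the child was delivered), and a
taxonomy table mapping ASVs to ranks.  This module parses and validates
them, applies the minimum-sequencing-depth exclusion, and pairs maternal
vaginal week-36 samples with child samples into the dyad sets on which all
transfer statistics are computed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: Allowed delivery-mode codes: vaginal birth, cesarean in labor, scheduled
#: cesarean.  "CS" is accepted in mode *sets* as shorthand for both CS codes.
DELIVERY_MODES = ("VAG", "CS-L", "CS-S")
COMPARTMENTS = ("vaginal", "fecal", "airway")
ROLES = ("mother", "child")

#: Sampling schedule.  Vaginal samples are coded by gestational week; child
#: samples by age in days.
VAGINAL_WEEKS = (24, 36)
CHILD_TIMEPOINTS = {"fecal": (7, 30, 300), "airway": (7, 30, 90)}

MIN_DEPTH_DEFAULT = 2000


@dataclass
class AbundanceTable:
    """Integer read-count matrix, samples as rows, ASVs as columns."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise ValidationError("counts must be non-negative integers")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.asv_ids)) != len(self.asv_ids):
            raise ValidationError("duplicate ASV ids")
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="depth")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        """Row-subset (and reorder) to ``ids``; unknown ids raise."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [pos[str(s)] for s in ids]
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None
        return AbundanceTable(list(ids), list(self.asv_ids), self.counts[rows])

    def select_asvs(self, ids: Sequence[str]) -> "AbundanceTable":
        pos = {a: i for i, a in enumerate(self.asv_ids)}
        try:
            cols = [pos[str(a)] for a in ids]
        except KeyError as exc:
            raise ValidationError(f"unknown ASV id {exc.args[0]!r}") from None
        return AbundanceTable(list(self.sample_ids), list(ids), self.counts[:, cols])


METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "dyad_id",
    "role",
    "compartment",
    "timepoint_days",
    "delivery",
)


@dataclass
class SampleMetadata:
    """Per-sample annotations; wraps a validated DataFrame."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"metadata missing required columns: {missing}")
        df = df.copy()
        for col in ("sample_id", "subject_id", "dyad_id", "role", "compartment", "delivery"):
            df[col] = df[col].astype(str)
        df["timepoint_days"] = pd.to_numeric(df["timepoint_days"], errors="raise").astype(int)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        bad = sorted(set(df["role"]) - set(ROLES))
        if bad:
            raise ValidationError(f"unknown roles {bad}; allowed: {list(ROLES)}")
        bad = sorted(set(df["compartment"]) - set(COMPARTMENTS))
        if bad:
            raise ValidationError(f"unknown compartments {bad}; allowed: {list(COMPARTMENTS)}")
        bad = sorted(set(df["delivery"]) - set(DELIVERY_MODES))
        if bad:
            raise ValidationError(f"unknown delivery codes {bad}; allowed: {list(DELIVERY_MODES)}")
        # schedule checks
        for comp, allowed in (("vaginal", VAGINAL_WEEKS),) + tuple(CHILD_TIMEPOINTS.items()):
            sel = df["compartment"] == comp
            bad_tp = sorted(set(df.loc[sel, "timepoint_days"]) - set(allowed))
            if bad_tp:
                raise ValidationError(
                    f"{comp} samples use timepoints {list(allowed)}; found {bad_tp}"
                )
        # each dyad has at most one mother subject, children resolve to her
        mothers = df[df["role"] == "mother"]
        n_mother_subjects = mothers.groupby("dyad_id")["subject_id"].nunique()
        multi = n_mother_subjects[n_mother_subjects > 1]
        if len(multi):
            raise ValidationError(f"dyad {multi.index[0]!r} has multiple mother subjects")
        child_dyads = set(df.loc[df["role"] == "child", "dyad_id"])
        orphan = sorted(child_dyads - set(mothers["dyad_id"]))
        if orphan:
            raise ValidationError(f"child dyads without a mother subject: {orphan[:5]}")
        # at most one vaginal week-36 sample per dyad
        w36 = df[(df["compartment"] == "vaginal") & (df["timepoint_days"] == 36)]
        dup36 = w36["dyad_id"].value_counts()
        dup36 = dup36[dup36 > 1]
        if len(dup36):
            raise ValidationError(f"dyad {dup36.index[0]!r} has multiple vaginal week-36 samples")
        self.frame = df.reset_index(drop=True)

    def samples_for(
        self,
        role: str | None = None,
        compartment: str | None = None,
        timepoint_days: int | None = None,
        deliveries: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        df = self.frame
        if role is not None:
            df = df[df["role"] == role]
        if compartment is not None:
            df = df[df["compartment"] == compartment]
        if timepoint_days is not None:
            df = df[df["timepoint_days"] == int(timepoint_days)]
        if deliveries is not None:
            df = df[df["delivery"].isin(expand_modes(deliveries))]
        return df


TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class TaxonomyTable:
    """ASV -> rank strings; ASVs with an empty order rank are 'unassigned'."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "asv_id" in df.columns:
            df = df.set_index("asv_id")
        missing = [c for c in TAXONOMY_RANKS if c not in df.columns]
        if missing:
            raise SchemaError(f"taxonomy missing rank columns: {missing}")
        df = df[list(TAXONOMY_RANKS)].fillna("").astype(str)
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValidationError("duplicate ASV ids in taxonomy")
        self.frame = df

    def order_of(self, asv_id: str) -> str:
        """Order rank for an ASV; '' if unassigned or unknown."""
        try:
            return self.frame.at[str(asv_id), "order"]
        except KeyError:
            return ""

    def orders(self, asv_ids: Sequence[str]) -> pd.Series:
        return pd.Series([self.order_of(a) for a in asv_ids], index=list(asv_ids), name="order")

    def unassigned(self) -> list[str]:
        return list(self.frame.index[self.frame["order"] == ""])


@dataclass(frozen=True)
class DyadSet:
    """Mother/child sample pairing for one stratum.

    The stratum is (child compartment, child timepoint in days, delivery-mode
    set); the mother side is always the vaginal week-36 sample.
    """

    compartment: str
    timepoint_days: int
    modes: frozenset[str]
    pairs: tuple[tuple[str, str], ...]
    dyad_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        mothers = [m for m, _ in self.pairs]
        children = [c for _, c in self.pairs]
        if len(set(mothers)) != len(mothers) or len(set(children)) != len(children):
            raise ValidationError("a sample appears in more than one dyad pair")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def mother_samples(self) -> list[str]:
        return [m for m, _ in self.pairs]

    @property
    def child_samples(self) -> list[str]:
        return [c for _, c in self.pairs]


def expand_modes(modes: Iterable[str] | str) -> frozenset[str]:
    """Normalize a delivery-mode set; 'CS' expands to {'CS-L', 'CS-S'}."""
    if isinstance(modes, str):
        modes = [modes]
    out: set[str] = set()
    for m in modes:
        if m == "CS":
            out.update({"CS-L", "CS-S"})
        elif m in DELIVERY_MODES:
            out.add(m)
        else:
            raise ValidationError(f"unknown delivery mode {m!r}; allowed: VAG, CS, CS-L, CS-S")
    return frozenset(out)


def read_count_table(path, format: str = "tsv", transpose: bool = False) -> AbundanceTable:
    """Read an ASV count table.

    TSV dialect: ASVs as rows, samples as columns, first column the ASV id
    (pass ``transpose=True`` for the samples-as-rows dialect).  BIOM input
    (HDF5 or JSON) is delegated to the biom-format package; BIOM tables are
    observation x sample, matching the untransposed TSV dialect.
    """
    if format == "biom":
        import biom

        table = biom.load_table(str(path))
        df = table.to_dataframe(dense=True)  # observations x samples
    elif format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except pd.errors.EmptyDataError:
            raise ParseError(f"{path}: empty count table") from None
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValidationError(f"{path}: duplicate ids in count table")
        values = np.empty(df.shape, dtype=np.int64)
        for j, col in enumerate(df.columns):
            try:
                numeric = pd.to_numeric(df[col], errors="raise")
            except (ValueError, TypeError):
                bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
                raise ParseError(
                    f"{path}: non-numeric cell {bad.iloc[0]!r} at row "
                    f"{bad.index[0]!r}, column {col!r}"
                ) from None
            if np.any(numeric != np.floor(numeric)):
                bad_row = df.index[np.asarray(numeric != np.floor(numeric))][0]
                raise ValidationError(
                    f"{path}: non-integer count at row {bad_row!r}, column {col!r}"
                )
            values[:, j] = numeric.astype(np.int64)
        df = pd.DataFrame(values, index=df.index, columns=df.columns)
    else:
        raise ValidationError(f"unknown count-table format {format!r}")
    if transpose:
        df = df.T
    # df is now ASVs x samples; AbundanceTable stores samples x ASVs
    return AbundanceTable(list(df.columns.astype(str)), list(df.index.astype(str)), df.T.to_numpy())


def read_sample_metadata(path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty metadata file") from None
    return SampleMetadata(df)


def read_taxonomy(path) -> TaxonomyTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty taxonomy file") from None
    if "asv_id" not in df.columns:
        raise SchemaError(f"{path}: taxonomy requires an 'asv_id' column")
    return TaxonomyTable(df)


def filter_min_depth(
    table: AbundanceTable, min_depth: int = MIN_DEPTH_DEFAULT
) -> tuple[AbundanceTable, list[str]]:
    """Drop samples with fewer than ``min_depth`` total reads.

    Returns the filtered table (ASV column set unchanged, even if some
    columns become all-zero) and the list of removed sample ids.
    """
    if min_depth < 1:
        raise ValidationError("min_depth must be >= 1")
    depths = table.counts.sum(axis=1)
    keep = depths >= min_depth
    removed = [s for s, k in zip(table.sample_ids, keep) if not k]
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return AbundanceTable(kept_ids, list(table.asv_ids), table.counts[keep]), removed


def build_dyads(
    meta: SampleMetadata,
    compartment: str,
    timepoint_days: int,
    modes: Iterable[str] | str,
    retained: Iterable[str] | None = None,
) -> DyadSet:
    """Pair each dyad's vaginal week-36 sample with its child sample.

    A dyad contributes a pair only when both the mother's week-36 vaginal
    sample and the child's sample at (compartment, timepoint) survive depth
    filtering (``retained``; None means all metadata samples).  Dyads whose
    delivery mode is outside ``modes`` are skipped.
    """
    if compartment not in CHILD_TIMEPOINTS:
        raise ValidationError(f"unknown child compartment {compartment!r}")
    if int(timepoint_days) not in CHILD_TIMEPOINTS[compartment]:
        raise ValidationError(
            f"{compartment} timepoint must be one of {CHILD_TIMEPOINTS[compartment]}"
        )
    mode_set = expand_modes(modes)
    retained_set = None if retained is None else {str(s) for s in retained}

    def ok(sample_id: str) -> bool:
        return retained_set is None or sample_id in retained_set

    w36 = meta.samples_for(role="mother", compartment="vaginal", timepoint_days=36)
    mother_by_dyad = dict(zip(w36["dyad_id"], w36["sample_id"]))
    kids = meta.samples_for(
        role="child", compartment=compartment, timepoint_days=int(timepoint_days)
    )
    kids = kids[kids["delivery"].isin(mode_set)]
    counts = kids["dyad_id"].value_counts()
    multi = counts[counts > 1]
    if len(multi):
        raise ValidationError(
            f"dyad {multi.index[0]!r} has multiple child samples at "
            f"({compartment}, day {timepoint_days})"
        )
    pairs: list[tuple[str, str]] = []
    dyads: list[str] = []
    for _, row in kids.sort_values("dyad_id").iterrows():
        m = mother_by_dyad.get(row["dyad_id"])
        if m is None or not ok(m) or not ok(row["sample_id"]):
            continue
        pairs.append((m, row["sample_id"]))
        dyads.append(row["dyad_id"])
    return DyadSet(compartment, int(timepoint_days), mode_set, tuple(pairs), tuple(dyads))


def enumerate_strata(split_cs: bool = False) -> list[tuple[str, int, frozenset[str]]]:
    """The full stratification: 2 compartments x 3 timepoints x modes.

    With ``split_cs=False`` the cesarean deliveries are pooled, giving the
    12 strata of the main analysis; ``split_cs=True`` separates CS-L and
    CS-S, giving 18.
    """
    mode_sets = (
        [frozenset({"VAG"}), frozenset({"CS-L", "CS-S"})]
        if not split_cs
        else [frozenset({"VAG"}), frozenset({"CS-L"}), frozenset({"CS-S"})]
    )
    out = []
    for comp in ("fecal", "airway"):
        for tp in CHILD_TIMEPOINTS[comp]:
            for ms in mode_sets:
                out.append((comp, tp, ms))
    return out


def write_table(rows, path) -> None:
    """Write result rows (DataFrame or iterable of dataclasses) as TSV."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if rows and dataclasses.is_dataclass(rows[0]):
            df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        else:
            df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def validate_inputs(
    table: AbundanceTable, meta: SampleMetadata, taxonomy: TaxonomyTable
) -> list[str]:
    """Joint consistency check of the three inputs; returns warnings.

    Hard violations (ids in the count table absent from metadata) raise;
    soft issues (ASVs without taxonomy, metadata samples without counts)
    are returned as human-readable warnings.
    """
    meta_ids = set(meta.frame["sample_id"])
    missing = [s for s in table.sample_ids if s not in meta_ids]
    if missing:
        raise ValidationError(f"count-table samples missing from metadata: {missing[:5]}")
    warnings: list[str] = []
    no_tax = [a for a in table.asv_ids if a not in taxonomy.frame.index]
    if no_tax:
        warnings.append(f"{len(no_tax)} ASVs missing from taxonomy")
    unassigned = set(taxonomy.unassigned()) & set(table.asv_ids)
    if unassigned:
        warnings.append(f"{len(unassigned)} ASVs have no order rank (excluded from order-level analysis)")
    extra = meta_ids - set(table.sample_ids)
    if extra:
        warnings.append(f"{len(extra)} metadata samples have no counts")
    return warnings
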