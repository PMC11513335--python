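"""Data model for time-resolved, multi-platform challenge metabolomics.

A study is a grid of time points organised in blocks (separate in-clinic
visits), with challenges (fasting, meal drinks, oral glucose/lipid loads,
exercise, cold stress) anchored at specific time points.  Measurements live
in a :class:`ProfileDataset`: a sparse (subject, time point, metabolite)
table per fluid and platform, where a missing value is an absent key, never
a sentinel number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    DuplicateKeyError,
    FormatError,
    LookupFailure,
)

FLUIDS = frozenset({"P", "U", "BA", "BC"})
PLATFORMS = frozenset({"nt-ms", "t-ms", "Lipidyzer", "NMR", "PTRMS", "ICR", "chem."})
SUPER_PATHWAYS = (
    "Amino acids",
    "Carbohydrates",
    "Cofactors and vitamins",
    "Energy",
    "Lipids",
    "Nucleotides",
    "Peptides",
    "Xenobiotics",
)
CHALLENGE_NAMES = ("FASTING", "SLDR", "SLD1", "OGTT", "SLD2", "OLTT", "PAT", "STRESS")

#: Transform tags a dataset may carry.
TRANSFORM_TAGS = ("raw", "log2", "zscore", "log2fc_block", "log2fc_challenge")

#: Default spacer (minutes) inserted between blocks on the concatenated study
#: axis.  The real inter-block break (weeks) is never represented as elapsed
#: time; a finite spacer merely keeps one monotone axis while guaranteeing
#: that windowed trajectory matching can never couple points across blocks.
DEFAULT_BLOCK_SPACER_MIN = 720.0


@dataclass(frozen=True)
class TimePoint:
    """One scheduled sampling time.

    ``clock_min`` is minutes since the first scheduled sample of the time
    point's own block (non-negative); blocks are separate visits and their
    clocks restart at zero.
    """

    index: int
    block: int
    day: int
    clock_min: float
    fluids_sampled: frozenset[str] = frozenset({"P"})

    def __post_init__(self) -> None:
        if self.block not in (1, 2):
            raise DomainError(f"block must be 1 or 2, got {self.block}")
        if self.clock_min < 0:
            raise DomainError(f"clock_min must be non-negative, got {self.clock_min}")
        bad = set(self.fluids_sampled) - FLUIDS
        if bad:
            raise DomainError(f"unknown fluids {sorted(bad)}")


@dataclass(frozen=True)
class ChallengeWindow:
    """A challenge with its baseline and tested time points.

    ``onset_clock_min`` is the challenge start on the block clock of the
    baseline time point; it may be negative (extended fasting starts the
    evening before sampling begins).
    """

    name: str
    baseline_tp: int
    tested_tps: tuple[int, ...]
    onset_clock_min: float
    period_label: str = ""

    def __post_init__(self) -> None:
        if self.name not in CHALLENGE_NAMES:
            raise DomainError(f"unknown challenge name {self.name!r}")
        if any(t <= self.baseline_tp for t in self.tested_tps):
            raise DomainError(
                f"{self.name}: baseline tp {self.baseline_tp} must precede all tested tps"
            )


@dataclass(frozen=True)
class MetaboliteInfo:
    """Catalog entry for one platform-qualified metabolite."""

    uid: str
    display_name: str
    fluid: str
    platform: str
    super_pathway: str = ""
    sub_pathway: str = ""
    external_ids: dict[str, str] = field(default_factory=dict)
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise DomainError(f"{self.uid}: unknown fluid tag {self.fluid!r}")
        if self.platform not in PLATFORMS:
            raise DomainError(f"{self.uid}: unknown platform tag {self.platform!r}")


class StudyDesign:
    """Time-point grid, challenge windows and subject roster."""

    def __init__(
        self,
        timepoints: list[TimePoint],
        challenges: list[ChallengeWindow],
        subjects: list[int],
        block_gap_note: bool = True,
    ) -> None:
        idx = [tp.index for tp in timepoints]
        if len(set(idx)) != len(idx):
            raise DomainError("time point indices must be unique")
        self.timepoints = sorted(timepoints, key=lambda tp: tp.index)
        self._by_index = {tp.index: tp for tp in self.timepoints}
        for block in (1, 2):
            tps = [tp for tp in self.timepoints if tp.block == block]
            clocks = [tp.clock_min for tp in tps]
            if any(b <= a for a, b in zip(clocks, clocks[1:])):
                raise DomainError(f"clock_min must strictly increase within block {block}")
        b1 = [tp.index for tp in self.timepoints if tp.block == 1]
        b2 = [tp.index for tp in self.timepoints if tp.block == 2]
        if b1 and b2 and max(b1) > min(b2):
            raise DomainError("block 2 indices must follow all block 1 indices")
        for ch in challenges:
            for t in (ch.baseline_tp, *ch.tested_tps):
                if t not in self._by_index:
                    raise DomainError(f"challenge {ch.name} references unknown tp {t}")
        self.challenges = list(challenges)
        self.subjects = list(subjects)
        self.block_gap_note = block_gap_note

    # -- lookups ---------------------------------------------------------

    def tp(self, index: int) -> TimePoint:
        try:
            return self._by_index[index]
        except KeyError:
            raise LookupFailure(f"unknown time point index {index}") from None

    @property
    def tp_indices(self) -> list[int]:
        return [tp.index for tp in self.timepoints]

    def challenge(self, name: str) -> ChallengeWindow:
        for ch in self.challenges:
            if ch.name == name.upper():
                return ch
        raise LookupFailure(f"unknown challenge {name!r}")

    def tps_for_fluid(self, fluid: str) -> list[int]:
        return [tp.index for tp in self.timepoints if fluid in tp.fluids_sampled]

    def block_of(self, tp_index: int) -> int:
        return self.tp(tp_index).block

    # -- the concatenated study axis ------------------------------------

    def axis_time(self, tp_index: int, spacer: float = DEFAULT_BLOCK_SPACER_MIN) -> float:
        """Minutes on the single monotone study axis (blocks concatenated)."""
        tp = self.tp(tp_index)
        if tp.block == 1:
            return tp.clock_min
        b1_end = max(
            (t.clock_min for t in self.timepoints if t.block == 1), default=-spacer
        )
        return b1_end + spacer + tp.clock_min

    def fasting_axis_span(
        self, spacer: float = DEFAULT_BLOCK_SPACER_MIN
    ) -> tuple[float, float] | None:
        """Axis interval covered by the extended-fasting challenge, or None."""
        try:
            ch = self.challenge("FASTING")
        except LookupFailure:
            return None
        tps = (ch.baseline_tp, *ch.tested_tps)
        times = [self.axis_time(t, spacer) for t in tps]
        return min(times), max(times)

    def challenge_onsets_in_block(self, block: int) -> list[float]:
        """Block-clock onset times of all challenges anchored in ``block``."""
        out = []
        for ch in self.challenges:
            if self.tp(ch.baseline_tp).block == block:
                out.append(ch.onset_clock_min)
        return out

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "timepoints": [
                {
                    "index": tp.index,
                    "block": tp.block,
                    "day": tp.day,
                    "clock_min": tp.clock_min,
                    "fluids_sampled": sorted(tp.fluids_sampled),
                }
                for tp in self.timepoints
            ],
            "challenges": [
                {
                    "name": ch.name,
                    "baseline_tp": ch.baseline_tp,
                    "tested_tps": list(ch.tested_tps),
                    "onset_clock_min": ch.onset_clock_min,
                    "period_label": ch.period_label,
                }
                for ch in self.challenges
            ],
            "subjects": self.subjects,
            "block_gap_note": self.block_gap_note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        tps = [
            TimePoint(
                index=t["index"],
                block=t["block"],
                day=t["day"],
                clock_min=t["clock_min"],
                fluids_sampled=frozenset(t.get("fluids_sampled", ["P"])),
            )
            for t in d["timepoints"]
        ]
        chs = [
            ChallengeWindow(
                name=c["name"],
                baseline_tp=c["baseline_tp"],
                tested_tps=tuple(c["tested_tps"]),
                onset_clock_min=c["onset_clock_min"],
                period_label=c.get("period_label", ""),
            )
            for c in d.get("challenges", [])
        ]
        return cls(tps, chs, list(d["subjects"]), d.get("block_gap_note", True))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StudyDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class ProfileDataset:
    """Long-format (subject, time point, metabolite) abundance store.

    Internally the observations sit in a wide ``pandas.DataFrame`` indexed by
    (subject, tp_index) with one column per metabolite uid; ``NaN`` marks a
    missing observation.  The public contract remains key-based: iteration
    and serialisation never emit sentinel values for missing entries.
    """

    def __init__(
        self,
        catalog: list[MetaboliteInfo],
        design: StudyDesign,
        values: pd.DataFrame,
        transform_tag: str = "raw",
    ) -> None:
        if transform_tag not in TRANSFORM_TAGS:
            raise DomainError(f"unknown transform tag {transform_tag!r}")
        uids = [m.uid for m in catalog]
        if len(set(uids)) != len(uids):
            raise DomainError("catalog uids must be unique")
        self.catalog = list(catalog)
        self._catalog_by_uid = {m.uid: m for m in catalog}
        self.design = design
        full_index = pd.MultiIndex.from_product(
            [design.subjects, design.tp_indices], names=["subject", "tp"]
        )
        self.values = values.reindex(index=full_index, columns=uids)
        self.transform_tag = transform_tag
        if transform_tag == "raw":
            arr = self.values.to_numpy()
            if np.any(arr[np.isfinite(arr)] <= 0):
                raise DomainError("raw abundances must be strictly positive")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_observations(
        cls,
        catalog: list[MetaboliteInfo],
        design: StudyDesign,
        observations: dict[tuple[int, int, str], float],
        transform_tag: str = "raw",
    ) -> "ProfileDataset":
        uids = [m.uid for m in catalog]
        idx = pd.MultiIndex.from_product(
            [design.subjects, design.tp_indices], names=["subject", "tp"]
        )
        values = pd.DataFrame(np.nan, index=idx, columns=uids)
        for (subj, tp, uid), v in observations.items():
            if uid not in values.columns:
                raise LookupFailure(f"unknown metabolite uid {uid!r}")
            if (subj, tp) not in idx:
                raise LookupFailure(f"unknown (subject, tp) pair ({subj}, {tp})")
            values.loc[(subj, tp), uid] = v
        return cls(catalog, design, values, transform_tag)

    # -- mapping-style access -------------------------------------------

    def metabolite(self, uid: str) -> MetaboliteInfo:
        try:
            return self._catalog_by_uid[uid]
        except KeyError:
            raise LookupFailure(f"unknown metabolite uid {uid!r}") from None

    @property
    def uids(self) -> list[str]:
        return [m.uid for m in self.catalog]

    def get(self, subject: int, tp: int, uid: str) -> float | None:
        v = self.values.at[(subject, tp), uid]
        return None if pd.isna(v) else float(v)

    def observations(self):
        """Iterate ``((subject, tp, uid), value)`` over non-missing entries."""
        stacked = self.values.stack()
        for (subj, tp, uid), v in stacked.items():
            yield (subj, tp, uid), float(v)

    @property
    def n_observations(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame, transform_tag: str | None = None):
        return ProfileDataset(
            self.catalog, self.design, values, transform_tag or self.transform_tag
        )

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        subjects=None,
        tps=None,
        uids=None,
        fluids=None,
        platforms=None,
    ) -> "ProfileDataset":
        """Restrict to the intersection of the given filters (None = all).

        An empty intersection is a valid empty dataset, but naming an id that
        does not exist at all raises a lookup error.
        """
        keep_subjects = self.design.subjects
        if subjects is not None:
            subjects = set(subjects)
            unknown = subjects - set(self.design.subjects)
            if unknown:
                raise LookupFailure(f"unknown subject(s) {sorted(unknown)}")
            keep_subjects = [s for s in self.design.subjects if s in subjects]
        keep_tp = self.design.tp_indices
        if tps is not None:
            tps = set(tps)
            unknown = tps - set(self.design.tp_indices)
            if unknown:
                raise LookupFailure(f"unknown time point(s) {sorted(unknown)}")
            keep_tp = [t for t in self.design.tp_indices if t in tps]
        keep = self.catalog
        if uids is not None:
            uids = set(uids)
            unknown = uids - set(self.uids)
            if unknown:
                raise LookupFailure(f"unknown uid(s) {sorted(unknown)}")
            keep = [m for m in keep if m.uid in uids]
        if fluids is not None:
            bad = set(fluids) - FLUIDS
            if bad:
                raise LookupFailure(f"unknown fluid(s) {sorted(bad)}")
            keep = [m for m in keep if m.fluid in set(fluids)]
        if platforms is not None:
            bad = set(platforms) - PLATFORMS
            if bad:
                raise LookupFailure(f"unknown platform(s) {sorted(bad)}")
            keep = [m for m in keep if m.platform in set(platforms)]

        design = StudyDesign(
            [tp for tp in self.design.timepoints if tp.index in set(keep_tp)],
            [
                ch
                for ch in self.design.challenges
                if ch.baseline_tp in set(keep_tp)
                and all(t in set(keep_tp) for t in ch.tested_tps)
            ],
            keep_subjects,
            self.design.block_gap_note,
        )
        vals = self.values.loc[
            self.values.index.get_level_values("subject").isin(keep_subjects)
            & self.values.index.get_level_values("tp").isin(keep_tp),
            [m.uid for m in keep],
        ]
        return ProfileDataset(keep, design, vals, self.transform_tag)

    # -- trajectories ----------------------------------------------------

    def trajectory(
        self,
        uid: str,
        subject: int | str = "mean",
        spacer: float = DEFAULT_BLOCK_SPACER_MIN,
        tp_range: tuple[int, int] | None = None,
    ) -> list[tuple[float, float]]:
        """Ordered (study-axis minutes, value) curve for one metabolite.

        ``subject="mean"`` averages non-missing values across subjects at
        each time point; time points with no observation at all are omitted.
        """
        if uid not in self._catalog_by_uid:
            raise LookupFailure(f"unknown metabolite uid {uid!r}")
        col = self.values[uid]
        if subject == "mean":
            series = col.groupby(level="tp").mean()
        else:
            if subject not in self.design.subjects:
                raise LookupFailure(f"unknown subject {subject}")
            series = col.xs(subject, level="subject")
        out = []
        for tp_index in self.design.tp_indices:
            if tp_range is not None and not (tp_range[0] <= tp_index <= tp_range[1]):
                continue
            v = series.get(tp_index, math.nan)
            if pd.notna(v):
                out.append((self.design.axis_time(tp_index, spacer), float(v)))
        return out

    # -- checks ----------------------------------------------------------

    def check_invariants(self, atol: float = 1e-8) -> None:
        if self.transform_tag == "zscore":
            mu = self.values.mean(axis=0, skipna=True)
            sd = self.values.std(axis=0, ddof=1, skipna=True)
            observed = self.values.notna().sum(axis=0) >= 2
            if not np.allclose(mu[observed], 0.0, atol=atol) or not np.allclose(
                sd[observed], 1.0, atol=atol
            ):
                raise DomainError("zscore dataset violates mean 0 / SD 1 invariant")


# ---------------------------------------------------------------------------
# Long-format I/O

LONG_COLUMNS = ["subject", "time_point", "metabolite_uid", "value"]


def read_long_table(path, catalog: list[MetaboliteInfo], design: StudyDesign) -> ProfileDataset:
    """Read a long-format TSV/CSV (subject, time_point, metabolite_uid, value).

    An empty value cell records a missing observation.  Rows naming unknown
    uids or time points are rejected, as are duplicate keys.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"metabolite_uid": str})
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing column(s) {missing_cols} in {path}")
    known_uids = {m.uid for m in catalog}
    known_tps = set(design.tp_indices)
    known_subjects = set(design.subjects)
    keys = list(zip(df["subject"], df["time_point"], df["metabolite_uid"]))
    seen: set = set()
    for k in keys:
        if k in seen:
            raise DuplicateKeyError(f"duplicate (subject, time_point, uid) key {k}")
        seen.add(k)
    obs: dict[tuple[int, int, str], float] = {}
    for (subj, tp, uid), v in zip(keys, df["value"]):
        subj, tp = int(subj), int(tp)
        if uid not in known_uids:
            raise LookupFailure(f"unknown metabolite uid {uid!r}")
        if tp not in known_tps:
            raise LookupFailure(f"unknown time point {tp}")
        if subj not in known_subjects:
            raise LookupFailure(f"unknown subject {subj}")
        if pd.notna(v):
            obs[(subj, tp, uid)] = float(v)
    return ProfileDataset.from_observations(catalog, design, obs, "raw")


def write_long_table(ds: ProfileDataset, path) -> None:
    """Write the dataset in long format; missing entries get empty value cells.

    Values are printed with 12 significant digits so a read/write round trip
    is bit-identical for such decimals.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = []
    for subj in ds.design.subjects:
        for tp in ds.design.tp_indices:
            for uid in ds.uids:
                v = ds.values.at[(subj, tp), uid]
                rows.append(
                    (subj, tp, uid, "" if pd.isna(v) else format(float(v), ".12g"))
                )
    out = pd.DataFrame(rows, columns=LONG_COLUMNS)
    # drop rows for entries that were never scheduled nor observed: keep all
    # keys of the full grid — missingness must round-trip, so emit every key
    out.to_csv(path, sep=sep, index=False)


def read_catalog(path) -> list[MetaboliteInfo]:
    """Read a catalog TSV (uid, display_name, fluid, platform, ...)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    needed = ["uid", "display_name", "fluid", "platform"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    out = []
    for _, row in df.iterrows():
        ext = {}
        for key in ("kegg", "hmdb", "chebi", "pubchem"):
            if row.get(key, ""):
                ext[key.upper() if key != "pubchem" else "PubChem"] = row[key]
        out.append(
            MetaboliteInfo(
                uid=row["uid"],
                display_name=row["display_name"],
                fluid=row["fluid"],
                platform=row["platform"],
                super_pathway=row.get("super_pathway", ""),
                sub_pathway=row.get("sub_pathway", ""),
                external_ids=ext,
                synonyms=tuple(s for s in row.get("synonyms", "").split("|") if s),
            )
        )
    return out


def write_catalog(catalog: list[MetaboliteInfo], path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    rows = []
    for m in catalog:
        rows.append(
            {
                "uid": m.uid,
                "display_name": m.display_name,
                "fluid": m.fluid,
                "platform": m.platform,
                "super_pathway": m.super_pathway,
                "sub_pathway": m.sub_pathway,
                "kegg": m.external_ids.get("KEGG", ""),
                "hmdb": m.external_ids.get("HMDB", ""),
                "chebi": m.external_ids.get("CHEBI", ""),
                "pubchem": m.external_ids.get("PubChem", ""),
                "synonyms": "|".join(m.synonyms),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
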