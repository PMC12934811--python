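"""Data model and IO for harmonized multi-study viability screens.

A screen dataset is a long-format table of viability measurements — one row
per (study, sample, drug, concentration, replicate) — plus per-sample and
per-drug annotation maps. A *curve* is the set of rows sharing
(study_id, sample_id, drug_id). Concentrations are stored in µM and handled in
log10(µM) internally. Viability is fraction-of-control; values in (1, 2] are
retained (over-control growth) and values above 2 are rejected.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyDatasetError, FormatError, ValidationError

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["study_id", "sample_id", "drug_id", "concentration_uM", "viability"]
MODEL_TYPES = ("PDC", "PDO", "PDXC", "cell_line")
EX_VIVO_TYPES = ("PDC", "PDO", "PDXC")


@dataclass
class SampleAnnotation:
    sample_id: str
    study_id: str = ""
    oncotree_code: str = ""
    primary_site: str = ""
    metastatic_site: str | None = None
    is_metastasis: bool = False
    model_type: str = "PDC"
    tmb: int | None = None

    def __post_init__(self):
        if self.model_type not in MODEL_TYPES:
            raise ValidationError(
                f"sample {self.sample_id}: model_type {self.model_type!r} "
                f"not in {MODEL_TYPES}"
            )
        if bool(self.metastatic_site) != bool(self.is_metastasis):
            raise ValidationError(
                f"sample {self.sample_id}: metastatic_site must be present "
                "iff is_metastasis"
            )

    @property
    def is_ex_vivo(self) -> bool:
        return self.model_type in EX_VIVO_TYPES


@dataclass
class DrugAnnotation:
    drug_id: str
    canonical_name: str = ""
    aliases: set = field(default_factory=set)
    mechanisms: list = field(default_factory=list)
    targets: set = field(default_factory=set)
    soc_diseases: set = field(default_factory=set)

    def __post_init__(self):
        if not self.canonical_name:
            self.canonical_name = self.drug_id
        self.aliases = set(self.aliases) | {self.canonical_name}

    @property
    def unannotated(self) -> bool:
        return len(self.mechanisms) == 0

    @property
    def first_mechanism(self) -> str | None:
        return self.mechanisms[0] if self.mechanisms else None


class ScreenDataset:
    """Validated long-format screen with annotation maps and curve indices."""

    def __init__(
        self,
        records: pd.DataFrame,
        samples: Mapping[str, SampleAnnotation] | None = None,
        drugs: Mapping[str, DrugAnnotation] | None = None,
    ):
        records = records.reset_index(drop=True).copy()
        if "replicate" not in records.columns:
            # uniqueness invariant: auto-index replicates 0..r-1 per dose
            records["replicate"] = records.groupby(
                ["study_id", "sample_id", "drug_id", "concentration_uM"], sort=False
            ).cumcount()
        self.records = records[RECORD_COLUMNS + ["replicate"]]
        self.samples = dict(samples) if samples else {}
        self.drugs = dict(drugs) if drugs else {}
        # every record's ids must resolve; create stub annotations if absent
        for sid, study in records[["sample_id", "study_id"]].drop_duplicates().itertuples(index=False):
            self.samples.setdefault(sid, SampleAnnotation(sample_id=sid, study_id=study))
        for did in records["drug_id"].unique():
            self.drugs.setdefault(did, DrugAnnotation(drug_id=did))

    # -- basic structure ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        a = self.records.sort_values(RECORD_COLUMNS + ["replicate"]).reset_index(drop=True)
        b = other.records.sort_values(RECORD_COLUMNS + ["replicate"]).reset_index(drop=True)
        return a.equals(b)

    @property
    def study_ids(self) -> list[str]:
        return sorted(self.records["study_id"].unique())

    @property
    def n_curves(self) -> int:
        return self.records.groupby(
            ["study_id", "sample_id", "drug_id"], sort=False
        ).ngroups

    def curves(self):
        """Iterate (study, sample, drug) -> sorted (log10 conc, viability) arrays."""
        for key, grp in self.records.groupby(["study_id", "sample_id", "drug_id"], sort=True):
            grp = grp.sort_values(["concentration_uM", "replicate"])
            yield key, (
                np.log10(grp["concentration_uM"].to_numpy(float)),
                grp["viability"].to_numpy(float),
            )

    def curve(self, study_id: str, sample_id: str, drug_id: str):
        grp = self.records[
            (self.records["study_id"] == study_id)
            & (self.records["sample_id"] == sample_id)
            & (self.records["drug_id"] == drug_id)
        ].sort_values(["concentration_uM", "replicate"])
        return (
            np.log10(grp["concentration_uM"].to_numpy(float)),
            grp["viability"].to_numpy(float),
        )

    def subset_drugs(self, drug_ids: Iterable[str]) -> "ScreenDataset":
        keep = set(drug_ids)
        rec = self.records[self.records["drug_id"].isin(keep)]
        return ScreenDataset(
            rec,
            samples=self.samples,
            drugs={d: a for d, a in self.drugs.items() if d in keep},
        )

    def subset_studies(self, study_ids: Iterable[str]) -> "ScreenDataset":
        keep = set(study_ids)
        rec = self.records[self.records["study_id"].isin(keep)]
        kept_samples = set(rec["sample_id"])
        return ScreenDataset(
            rec,
            samples={s: a for s, a in self.samples.items() if s in kept_samples},
            drugs=self.drugs,
        )


def _validate_records(df: pd.DataFrame, strict: bool) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    df = df.copy()
    for col in ("concentration_uM", "viability"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    bad_conc = ~(df["concentration_uM"] > 0)
    bad_viab = ~df["viability"].between(0.0, 2.0)
    bad = bad_conc | bad_viab | df["concentration_uM"].isna() | df["viability"].isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based + header line
        msg = (
            f"{int(bad.sum())} invalid rows (concentration must be > 0, "
            f"viability in [0, 2]); file lines: {rows[:20]}"
        )
        if strict:
            raise ValidationError(msg)
        logger.warning("dropping %s", msg)
        df = df[~bad]
    return df


def _auto_index_replicates(df: pd.DataFrame) -> pd.DataFrame:
    if "replicate" in df.columns:
        df = df.copy()
        df["replicate"] = df["replicate"].fillna(0).astype(int)
    else:
        df = df.copy()
        df["replicate"] = df.groupby(
            ["study_id", "sample_id", "drug_id", "concentration_uM"], sort=False
        ).cumcount()
    dupes = df.duplicated(
        ["study_id", "sample_id", "drug_id", "concentration_uM", "replicate"]
    )
    if dupes.any():
        raise ValidationError(
            f"{int(dupes.sum())} duplicate (study, sample, drug, concentration, "
            "replicate) rows"
        )
    return df


def load_viability_table(
    path,
    samples: Mapping[str, SampleAnnotation] | None = None,
    drugs: Mapping[str, DrugAnnotation] | None = None,
    strict: bool = True,
) -> ScreenDataset:
    """Read a tab-separated long-format viability table (gzip accepted)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"study_id": str, "sample_id": str, "drug_id": str},
        float_precision="round_trip",
    )
    df = _validate_records(df, strict=strict)
    df = _auto_index_replicates(df)
    return ScreenDataset(df, samples=samples, drugs=drugs)


def write_dataset(ds: ScreenDataset, path) -> None:
    out = ds.records.sort_values(RECORD_COLUMNS + ["replicate"])
    # %.17g keeps the load(write(ds)) round trip bit-exact for doubles
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_sample_annotations(samples: Mapping[str, SampleAnnotation], path) -> None:
    rows = [dataclasses.asdict(s) for s in samples.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_sample_annotations(path) -> dict[str, SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "study_id": str})
    out = {}
    for row in df.to_dict("records"):
        met = row.get("metastatic_site")
        if pd.isna(met) or met == "":
            met = None
        tmb = row.get("tmb")
        tmb = None if tmb is None or pd.isna(tmb) else int(tmb)
        out[row["sample_id"]] = SampleAnnotation(
            sample_id=row["sample_id"],
            study_id=row.get("study_id", "") or "",
            oncotree_code=row.get("oncotree_code", "") or "",
            primary_site=row.get("primary_site", "") or "",
            metastatic_site=met,
            is_metastasis=bool(row.get("is_metastasis", False)),
            model_type=row.get("model_type", "PDC"),
            tmb=tmb,
        )
    return out


def write_drug_annotations(drugs: Mapping[str, DrugAnnotation], path) -> None:
    rows = []
    for d in drugs.values():
        rows.append(
            {
                "drug_id": d.drug_id,
                "canonical_name": d.canonical_name,
                "aliases": "|".join(sorted(d.aliases)),
                "mechanisms": "|".join(d.mechanisms),
                "targets": "|".join(sorted(d.targets)),
                "soc_diseases": "|".join(sorted(d.soc_diseases)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_drug_annotations(path) -> dict[str, DrugAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    for row in df.to_dict("records"):
        split = lambda s: [x for x in s.split("|") if x]  # noqa: E731
        out[row["drug_id"]] = DrugAnnotation(
            drug_id=row["drug_id"],
            canonical_name=row.get("canonical_name", "") or row["drug_id"],
            aliases=set(split(row.get("aliases", ""))),
            mechanisms=split(row.get("mechanisms", "")),
            targets=set(split(row.get("targets", ""))),
            soc_diseases=set(split(row.get("soc_diseases", ""))),
        )
    return out


def summarize_dataset(ds: ScreenDataset) -> dict:
    """Counts per study, per-drug study occupancy, and panel overlap fractions.

    Returns a dict with keys ``per_study`` (DataFrame), ``occupancy`` (Series:
    number of studies -> number of drugs), ``single_study_pct`` (percentage of
    drugs screened in exactly one study), and ``overlap`` (DataFrame of pairwise
    Jaccard-style panel overlap = |A ∩ B| / min(|A|, |B|)).
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot summarize an empty dataset")
    rec = ds.records
    per_study = rec.groupby("study_id").agg(
        n_samples=("sample_id", "nunique"),
        n_drugs=("drug_id", "nunique"),
        n_measurements=("viability", "size"),
    )
    per_study["n_curves"] = (
        rec.drop_duplicates(["study_id", "sample_id", "drug_id"])
        .groupby("study_id")
        .size()
    )
    occ = rec.groupby("drug_id")["study_id"].nunique()
    occupancy = occ.value_counts().sort_index()
    single_study_pct = 100.0 * float((occ == 1).sum()) / float(len(occ))
    panels = {s: set(g["drug_id"]) for s, g in rec.groupby("study_id")}
    studies = sorted(panels)
    overlap = pd.DataFrame(
        [
            [
                len(panels[a] & panels[b]) / min(len(panels[a]), len(panels[b]))
                for b in studies
            ]
            for a in studies
        ],
        index=studies,
        columns=studies,
    )
    return {
        "per_study": per_study,
        "occupancy": occupancy,
        "single_study_pct": single_study_pct,
        "overlap": overlap,
    }


@dataclass(frozen=True)
class DoseGrid:
    """K points uniformly spaced in log10(µM) covering a drug's observed range."""

    drug_id: str
    log10_points: np.ndarray

    def __post_init__(self):
        pts = np.asarray(self.log10_points, float)
        if np.any(np.diff(pts) <= 0):
            raise ConfigError(f"dose grid for {self.drug_id} must be strictly increasing")
        object.__setattr__(self, "log10_points", pts)

    @property
    def K(self) -> int:
        return len(self.log10_points)

    def interp_weights(self, log10_conc: np.ndarray):
        """Indices (lo) and weights for linear interpolation; clamped at ends."""
        x = np.asarray(log10_conc, float)
        g = self.log10_points
        lo = np.clip(np.searchsorted(g, x, side="right") - 1, 0, self.K - 2)
        w = (x - g[lo]) / (g[lo + 1] - g[lo])
        w = np.clip(w, 0.0, 1.0)  # flat extrapolation beyond grid ends
        return lo, w


def build_dose_grids(
    ds: ScreenDataset, K: int = 10, single_dose_span: float = 1.0
) -> dict[str, DoseGrid]:
    """Per-drug uniform log10 grids pooled across studies.

    Drugs observed at a single concentration c get a grid spanning
    [log10(c) − span, log10(c) + span].
    """
    if K < 2:
        raise ConfigError(f"K must be >= 2, got {K}")
    if single_dose_span <= 0:
        raise ConfigError("single_dose_span must be positive")
    grids = {}
    conc = ds.records.groupby("drug_id")["concentration_uM"]
    for drug_id, (cmin, cmax) in conc.agg(["min", "max"]).iterrows():
        lo, hi = np.log10(cmin), np.log10(cmax)
        if hi - lo < 1e-12:
            lo, hi = lo - single_dose_span, hi + single_dose_span
        grids[drug_id] = DoseGrid(drug_id, np.linspace(lo, hi, K))
    return grids
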