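"""Readers and writers for taxonomic / gene-family profile tables and sample metadata.

The pipeline consumes the tab-separated outputs of standard shotgun-metagenomic
profilers: per-sample species relative abundances (clade column with
``k__|p__|...|s__`` lineage syntax) and UniRef90 gene-family abundance tables
that may carry ``|g__Genus.s__species``-stratified rows.  Everything is
normalised into a single in-memory container, :class:`AbundanceTable`, with
samples as rows and features as columns.
"""

from __future__ import annotations

import gzip
import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANK_PREFIXES = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
    "strain": "t",
}
_VALID_PREFIX = set("kpcofgst")

#: Binary/continuous covariates adjusted for throughout (delivery-record and
#: questionnaire items collected at recruitment and follow-up).
COVARIATES = {
    "gestational_age": "continuous",
    "sex_male": "binary",
    "peripartum_antibiotics": "binary",
    "csection": "binary",
    "exclusive_breastfeeding": "binary",
    "maternal_smoking": "binary",
    "maternal_age": "continuous",
    "paternal_age": "continuous",
    "married": "binary",
    "parous": "binary",
    "maternal_education": "binary",
    "age_at_srs2": "continuous",
}

DEFAULT_MISSING_CODES = ("", "NA", "NaN")


class ProfileParseError(ValueError):
    """Raised when a profile or metadata file violates its format contract."""


@dataclass
class AbundanceTable:
    """Samples x features matrix of non-negative relative abundances.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature ids (species name
        or UniRef90 id) as columns.
    feature_kind:
        ``"taxon"`` or ``"genefamily"``.
    stratified:
        Optional per-feature taxon decomposition: feature id -> DataFrame
        (samples x contributing taxa).  Strata of a feature sum to at most the
        unstratified value in every sample.
    unmapped:
        Optional per-sample mass of UNMAPPED/UNGROUPED reads, kept out of the
        feature set but available for the normalisation denominator.
    zero_samples:
        Sample ids whose profile is entirely zero (flagged, not dropped).
    """

    data: pd.DataFrame
    feature_kind: str = "taxon"
    stratified: dict[str, pd.DataFrame] | None = None
    unmapped: pd.Series | None = None
    zero_samples: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.stratified:
            for fid, strata in self.stratified.items():
                if fid not in self.data.columns:
                    raise ValueError(f"stratified feature {fid!r} has no parent column")
                excess = strata.sum(axis=1) - self.data[fid].reindex(strata.index)
                if (excess > 1e-6).any():
                    raise ValueError(f"strata of {fid!r} exceed the unstratified value")

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            data=self.data.copy(),
            feature_kind=self.feature_kind,
            stratified={k: v.copy() for k, v in self.stratified.items()}
            if self.stratified
            else None,
            unmapped=self.unmapped.copy() if self.unmapped is not None else None,
            zero_samples=list(self.zero_samples),
        )


@dataclass
class GeneSetCatalog:
    """Named neuroactive gene sets resolved from KEGG Orthologs to UniRef90 ids."""

    sets: dict[str, set[str]]
    ko_members: dict[str, set[str]]
    mapping: dict[str, set[str]]
    unmapped_ko_counts: dict[str, int] = field(default_factory=dict)
    empty_sets: list[str] = field(default_factory=list)

    @property
    def set_names(self) -> list[str]:
        return list(self.sets)


def _read_lines(path) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh]


def _split_header(lines: list[str]) -> tuple[list[str], list[str]]:
    """Return (header fields, data lines), tolerating '#'-prefixed headers."""
    header = None
    data: list[str] = []
    for ln in lines:
        if not ln.strip():
            continue
        if ln.startswith("#"):
            if "\t" in ln:
                header = ln.lstrip("#").strip()
            continue
        if header is None:
            header = ln
            continue
        data.append(ln)
    if header is None:
        raise ProfileParseError("no header line found")
    return header.split("\t"), data


def _check_sample_columns(fields: list[str], path) -> list[str]:
    samples = fields[1:]
    seen = set()
    for s in samples:
        if s in seen:
            raise ProfileParseError(f"duplicate sample column {s!r} in {path}")
        seen.add(s)
    return samples


def _maybe_percent_to_proportion(df: pd.DataFrame) -> pd.DataFrame:
    # MetaPhlAn emits percent; synthetic fixtures emit proportions.  Any
    # sample summing above 1.5 marks the whole file as percent-scaled.
    if df.shape[1] and (df.sum(axis=0) > 1.5).any():
        return df / 100.0
    return df


def read_taxonomic_profiles(path, level: str = "species") -> AbundanceTable:
    """Read a MetaPhlAn-style clade x sample TSV, keeping rows at ``level``.

    Percent inputs are rescaled to proportions (auto-detected).  Feature ids
    are the rank-level names with the ``s__`` prefix stripped, so species
    match across cohorts by exact string equality.
    """
    if level not in RANK_PREFIXES:
        raise ValueError(f"unknown taxonomic rank {level!r}")
    want = RANK_PREFIXES[level]
    fields, data_lines = _split_header(_read_lines(path))
    samples = _check_sample_columns(fields, path)

    rows: dict[str, list[float]] = {}
    for i, ln in enumerate(data_lines, start=1):
        parts = ln.split("\t")
        clade = parts[0]
        tokens = clade.split("|")
        for tok in tokens:
            if len(tok) < 3 or tok[1:3] != "__" or tok[0] not in _VALID_PREFIX:
                raise ProfileParseError(
                    f"malformed lineage string {clade!r} at data line {i} of {path}"
                )
        last = tokens[-1]
        if last[0] != want:
            continue
        name = last[3:]
        vals = [float(v) for v in parts[1 : len(samples) + 1]]
        if name in rows:
            raise ProfileParseError(f"duplicate {level} row {name!r} in {path}")
        rows[name] = vals

    df = pd.DataFrame(rows, index=samples, dtype=float)
    if df.empty:
        logger.warning("no rows at rank %r found in %s", level, path)
        df = pd.DataFrame(index=samples, dtype=float)
    df = _maybe_percent_to_proportion(df.T).T
    if (df.values < 0).any():
        raise ProfileParseError(f"negative abundance in {path}")
    table = AbundanceTable(data=df, feature_kind="taxon")
    table.zero_samples = list(df.index[df.sum(axis=1) == 0]) if df.shape[1] else list(df.index)
    return table


def write_taxonomic_profiles(table: AbundanceTable, path) -> None:
    """Write species proportions back out in single-token ``s__Name`` syntax."""
    with open(path, "w") as fh:
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        for fid in table.feature_ids:
            vals = "\t".join(repr(float(v)) for v in table.data[fid].values)
            fh.write(f"s__{fid}\t{vals}\n")


def read_genefamily_profiles(path, keep_stratified: bool = True) -> AbundanceTable:
    """Read a HUMAnN-style UniRef90 gene-family TSV.

    Unstratified rows populate the value matrix; ``UniRef90_X|g__G.s__s`` rows
    populate the per-taxon stratification.  UNMAPPED/UNGROUPED rows are
    excluded from the feature set but their per-sample mass is recorded.  A
    stratified row without a matching unstratified parent triggers a warning
    and the parent is synthesised as the sum of its strata.
    """
    fields, data_lines = _split_header(_read_lines(path))
    samples = _check_sample_columns(fields, path)

    parents: dict[str, np.ndarray] = {}
    strata: dict[str, dict[str, np.ndarray]] = {}
    unmapped = np.zeros(len(samples))
    for ln in data_lines:
        parts = ln.split("\t")
        fid = parts[0]
        vals = np.array([float(v) for v in parts[1 : len(samples) + 1]])
        base = fid.split("|", 1)[0]
        if base in ("UNMAPPED", "UNGROUPED"):
            if "|" not in fid:
                unmapped += vals
            continue
        if "|" in fid:
            taxon = fid.split("|", 1)[1]
            strata.setdefault(base, {})[taxon] = vals
        else:
            parents[base] = vals

    for base, tax in strata.items():
        if base not in parents:
            warnings.warn(
                f"stratified rows for {base} lack an unstratified parent; "
                "synthesising the parent as the sum of strata",
                stacklevel=2,
            )
            parents[base] = np.sum(list(tax.values()), axis=0)

    df = pd.DataFrame(parents, index=samples, dtype=float)
    strat_map = None
    if keep_stratified and strata:
        strat_map = {
            base: pd.DataFrame(tax, index=samples, dtype=float)
            for base, tax in strata.items()
        }
    table = AbundanceTable(
        data=df,
        feature_kind="genefamily",
        stratified=strat_map,
        unmapped=pd.Series(unmapped, index=samples) if unmapped.any() else None,
    )
    table.validate()
    return table


def write_genefamily_profiles(table: AbundanceTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_family\t" + "\t".join(table.sample_ids) + "\n")
        if table.unmapped is not None:
            vals = "\t".join(repr(float(v)) for v in table.unmapped.values)
            fh.write(f"UNMAPPED\t{vals}\n")
        for fid in table.feature_ids:
            vals = "\t".join(repr(float(v)) for v in table.data[fid].values)
            fh.write(f"{fid}\t{vals}\n")
            if table.stratified and fid in table.stratified:
                sub = table.stratified[fid]
                for taxon in sub.columns:
                    tv = "\t".join(repr(float(v)) for v in sub[taxon].values)
                    fh.write(f"{fid}|{taxon}\t{tv}\n")


def tss_normalize(table: AbundanceTable, include_unmapped: bool = True) -> AbundanceTable:
    """Total-sum scale every sample to proportions.

    All-zero samples stay zero and are flagged in ``zero_samples``.  When the
    table carries UNMAPPED mass and ``include_unmapped`` is true, that mass
    stays in the denominator so feature proportions reflect community-wide
    relative abundance (sample sums are then below one).  Idempotent.
    """
    if (table.data.values < 0).any():
        raise ValueError("negative abundance value")
    out = table.copy()
    denom = out.data.sum(axis=1)
    if include_unmapped and out.unmapped is not None:
        denom = denom + out.unmapped
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero sample(s) left unnormalised", stacklevel=2)
    safe = denom.replace(0, 1.0)
    out.data = out.data.div(safe, axis=0)
    if out.unmapped is not None:
        out.unmapped = out.unmapped / safe
    if out.stratified:
        out.stratified = {
            fid: sub.div(safe.reindex(sub.index), axis=0) for fid, sub in out.stratified.items()
        }
    out.zero_samples = sorted(set(out.zero_samples) | set(denom.index[zero]))
    return out


# ---------------------------------------------------------------------------
# sample metadata


def default_schema() -> dict:
    """Column schema for the standard covariate set, extendable by callers."""
    schema = {
        "subject_id": {"type": "string"},
        "sample_id": {"type": "string"},
        "cohort": {"type": "categorical", "levels": ["A", "B"]},
        "window": {"type": "categorical", "levels": ["early", "late"]},
        "sample_age": {"type": "continuous"},
        "srs2_tscore": {"type": "continuous"},
    }
    for cov, kind in COVARIATES.items():
        schema[cov] = {"type": kind}
    return schema


def read_metadata(path, schema: dict | None = None,
                  missing_codes: tuple[str, ...] = DEFAULT_MISSING_CODES) -> pd.DataFrame:
    """Read a delimited sample-metadata table into a typed DataFrame.

    Missing cells (blank or any code in ``missing_codes``) become NaN; the
    missingness mask is therefore ``df[cov].isna()``.  Binary covariates must
    be coded 0/1.  ``subject_id`` must be unique within cohort and window.
    """
    schema = schema or default_schema()
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("subject_id", "srs2_tscore"):
        if col not in df.columns:
            raise ProfileParseError(f"mandatory column {col!r} missing from {path}")
    df = df.replace(list(missing_codes), np.nan)

    for col, spec in schema.items():
        if col not in df.columns:
            continue
        kind = spec["type"]
        if kind in ("continuous", "binary"):
            df[col] = pd.to_numeric(df[col], errors="raise")
            if kind == "binary":
                bad = df[col].dropna().loc[lambda s: ~s.isin([0, 1])]
                if len(bad):
                    raise ProfileParseError(
                        f"non-binary levels in {col!r} at rows {bad.index.tolist()}"
                    )
        elif kind == "categorical":
            levels = spec.get("levels")
            if levels is not None:
                bad = df[col].dropna().loc[lambda s: ~s.isin(levels)]
                if len(bad):
                    raise ProfileParseError(
                        f"unknown level(s) {sorted(set(bad))} in {col!r} "
                        f"at rows {bad.index.tolist()}"
                    )

    keys = ["subject_id"]
    for extra in ("cohort", "window"):
        if extra in df.columns:
            keys.append(extra)
    if df.duplicated(subset=keys).any():
        dupes = df.loc[df.duplicated(subset=keys), "subject_id"].tolist()
        raise ProfileParseError(f"duplicate subject ids within cohort/window: {dupes}")
    return df


def missingness_summary(metadata: pd.DataFrame, covariates=None) -> pd.Series:
    """Count of missing values per covariate column."""
    cols = [c for c in (covariates or COVARIATES) if c in metadata.columns]
    return metadata[cols].isna().sum()


# ---------------------------------------------------------------------------
# gene-set catalog


def load_geneset_catalog(sets_path, mapping_path) -> GeneSetCatalog:
    """Resolve a KO-based gene-set catalog to UniRef90 membership.

    ``sets_path``: TSV with columns (set_name, KO), one pair per line.
    ``mapping_path``: TSV with columns (KO, UniRef90), one pair per line,
    optionally gzipped.  A KO absent from the mapping is counted per set, not
    fatal; a set whose every KO is unmapped is flagged empty, not dropped.
    """
    ko_members: dict[str, set[str]] = {}
    for ln in _read_lines(sets_path):
        if not ln.strip() or ln.startswith("#"):
            continue
        name, ko = ln.split("\t")[:2]
        ko_members.setdefault(name, set()).add(ko)

    mapping: dict[str, set[str]] = {}
    for ln in _read_lines(mapping_path):
        if not ln.strip() or ln.startswith("#"):
            continue
        ko, uniref = ln.split("\t")[:2]
        mapping.setdefault(ko, set()).add(uniref)

    sets: dict[str, set[str]] = {}
    unmapped_counts: dict[str, int] = {}
    empty: list[str] = []
    for name, kos in ko_members.items():
        members: set[str] = set()
        n_unmapped = 0
        for ko in kos:
            if ko in mapping:
                members |= mapping[ko]
            else:
                n_unmapped += 1
        sets[name] = members
        unmapped_counts[name] = n_unmapped
        if not members:
            empty.append(name)
            logger.warning("gene set %r has no mapped UniRef90 members", name)
    return GeneSetCatalog(
        sets=sets,
        ko_members=ko_members,
        mapping=mapping,
        unmapped_ko_counts=unmapped_counts,
        empty_sets=empty,
    )


def write_geneset_catalog(catalog: GeneSetCatalog, sets_path, mapping_path) -> None:
    with open(sets_path, "w") as fh:
        for name, kos in catalog.ko_members.items():
            for ko in sorted(kos):
                fh.write(f"{name}\t{ko}\n")
    with open(mapping_path, "w") as fh:
        for ko, unirefs in catalog.mapping.items():
            for u in sorted(unirefs):
                fh.write(f"{ko}\t{u}\n")
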