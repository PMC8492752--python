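"""OTU-table processing, functional guilds, and qPCR absolute abundance.

Works on a light container (:class:`OtuTable`) holding a samples x OTUs count
matrix, per-OTU taxonomy lineage strings, and per-sample metadata (core, lake,
zone, depth).  Counts are integers straight off the sequencer, or non-negative
reals after replicate averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform


class CommunityError(ValueError):
    pass


@dataclass
class OtuTable:
    """Samples x OTUs counts with taxonomy and sample metadata.

    counts:      DataFrame, rows = samples, columns = OTU ids.
    taxonomy:    Series indexed by OTU id, semicolon-delimited lineage string
                 (domain;phylum;class;order;family;genus).
    sample_meta: DataFrame indexed by sample id with columns
                 core, lake, zone, depth_cm.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise CommunityError("duplicate sample or OTU ids")
        if not self.counts.columns.isin(self.taxonomy.index).all():
            raise CommunityError("taxonomy missing for some OTUs")
        if (np.asarray(self.counts) < 0).any():
            raise CommunityError("negative counts")
        self.taxonomy = self.taxonomy.loc[self.counts.columns]
        self.sample_meta = self.sample_meta.loc[self.counts.index]

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def otus(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (fractions summing to 1)."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise CommunityError("sample with zero total count")
        return self.counts.div(totals, axis=0)

    def subset_samples(self, keep: Sequence[str]) -> "OtuTable":
        keep = list(keep)
        return replace(
            self,
            counts=self.counts.loc[keep],
            taxonomy=self.taxonomy,
            sample_meta=self.sample_meta.loc[keep],
        )


# ----------------------------------------------------------------------
# rarefaction and replicate averaging
# ----------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int = 3000, seed: int | None = 0) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    Deterministic for a fixed ``seed``.
    """
    if depth < 1:
        raise CommunityError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise CommunityError("all samples fall below the rarefaction depth")
    if len(dropped):
        warnings.warn(
            f"dropped {len(dropped)} sample(s) below depth {depth}: "
            + ", ".join(map(str, dropped))
        )
    rows = []
    for s in keep:
        counts = table.counts.loc[s].to_numpy(dtype=np.int64)
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    rare = pd.DataFrame(rows, index=keep, columns=table.counts.columns)
    return OtuTable(rare, table.taxonomy, table.sample_meta.loc[keep])


def average_replicates(table: OtuTable, pairing: Mapping[str, str]) -> OtuTable:
    """Average OTU counts within replicate pairs.

    ``pairing`` maps sample id -> replicate-group id; groups must have one or
    two members (the field design ran at most duplicate extractions).  Metadata
    for a pair must agree; the group id becomes the output sample id.
    """
    groups = pd.Series({s: pairing.get(s, s) for s in table.samples})
    sizes = groups.value_counts()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index.tolist()
        raise CommunityError(f"replicate groups larger than 2: {bad}")
    counts = table.counts.groupby(groups).mean()
    meta = table.sample_meta.groupby(groups).first()
    check = table.sample_meta.groupby(groups).nunique()
    if (check > 1).any().any():
        raise CommunityError("replicate pair with conflicting metadata")
    return OtuTable(counts, table.taxonomy, meta)


# ----------------------------------------------------------------------
# Bray-Curtis
# ----------------------------------------------------------------------

def braycurtis(table: OtuTable, transform: str = "sqrt") -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix on (optionally sqrt-) transformed counts.

    Returns a labelled square DataFrame; ``100 * (1 - d)`` gives the percent
    similarity convention used by marine-ecology toolkits.
    """
    if len(table.samples) < 2:
        raise CommunityError("need at least two samples")
    x = table.counts.to_numpy(dtype=float)
    if (x.sum(axis=1) == 0).any():
        raise CommunityError("all-zero sample")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform not in (None, "none"):
        raise CommunityError(f"unknown transform {transform!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)


# ----------------------------------------------------------------------
# functional guilds
# ----------------------------------------------------------------------

DEFAULT_GUILDS: dict[str, list[str]] = {
    # seeded from well-known clade names; editable via YAML (io.read_guilds)
    "methanogen": [
        "Methanobacteriales", "Methanococcales", "Methanomicrobiales",
        "Methanosarcinales", "Methanocellales", "Methanopyrales",
        "Methanomassiliicoccales", "Methanofastidiosales",
        "Methanoregula", "Methanosaeta",
    ],
    "ANME": ["ANME-1", "ANME-2", "ANME-3", "ANME"],
    "aerobic_methanotroph": [
        "Methylococcales", "Methylococcaceae", "Methylocystaceae",
        "Methylomonas", "Methylobacter",
    ],
    "syntrophaceae": ["Syntrophaceae"],
}


def _match_guilds(
    taxonomy: pd.Series, guilds: Mapping[str, Sequence[str]]
) -> dict[str, pd.Index]:
    """Resolve each guild to OTU ids by case-insensitive substring match.

    A taxon may belong to at most one guild; first match in guild order wins
    and a collision raises.
    """
    assigned: dict[str, str] = {}
    members: dict[str, list[str]] = {g: [] for g in guilds}
    lowered = taxonomy.str.lower()
    for guild, patterns in guilds.items():
        if not patterns:
            raise CommunityError(f"guild {guild!r} has no patterns")
        mask = np.zeros(len(taxonomy), dtype=bool)
        for p in patterns:
            mask |= lowered.str.contains(p.lower(), regex=False).to_numpy()
        for otu in taxonomy.index[mask]:
            if otu in assigned and assigned[otu] != guild:
                raise CommunityError(
                    f"OTU {otu} matches both {assigned[otu]} and {guild}"
                )
            if otu not in assigned:
                assigned[otu] = guild
                members[guild].append(otu)
    return {g: pd.Index(m) for g, m in members.items()}


@dataclass
class GuildTestResult:
    guild: str
    t_stat: float
    t_p: float
    anova_F: float
    anova_p: float


def guild_abundance(
    table: OtuTable,
    guilds: Mapping[str, Sequence[str]] | None = None,
    group_col: str = "zone",
) -> tuple[pd.DataFrame, list[GuildTestResult]]:
    """Per-sample guild relative abundances (percent) and group contrasts.

    Returns a samples x guilds DataFrame of percent relative abundances, and
    a two-group comparison (two-tailed Welch-free Student t and one-way ANOVA;
    with two groups F = t^2) per guild on the ``group_col`` metadata column.
    """
    guilds = dict(guilds or DEFAULT_GUILDS)
    members = _match_guilds(table.taxonomy, guilds)
    rel = table.relative_abundance()
    cols = {}
    for g, otus in members.items():
        if len(otus) == 0:
            warnings.warn(f"guild {g!r} matched no OTUs; reporting zeros")
            cols[g] = pd.Series(0.0, index=table.samples)
        else:
            cols[g] = rel[otus].sum(axis=1) * 100.0
    abund = pd.DataFrame(cols)

    tests: list[GuildTestResult] = []
    labels = table.sample_meta[group_col]
    levels = sorted(labels.unique())
    if len(levels) == 2:
        a, b = levels
        for g in abund.columns:
            xa = abund.loc[labels == a, g]
            xb = abund.loc[labels == b, g]
            t, tp = stats.ttest_ind(xa, xb)
            F, fp = stats.f_oneway(xa, xb)
            tests.append(GuildTestResult(g, float(t), float(tp), float(F), float(fp)))
    return abund, tests


# ----------------------------------------------------------------------
# qPCR absolute quantification
# ----------------------------------------------------------------------

AVOGADRO = 6.022e23


@dataclass
class QpcrStandard:
    """The genomic-DNA standard used to build the Ct calibration curve."""

    genome_size_bp: int = 4_686_137
    gene_copies_per_genome: int = 7
    stock_ng_per_uL: float = 20.0
    dilutions: Sequence[float] = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)
    mean_bp_mass: float = 650.0  # g/mol per base pair

    def genome_mass_g(self) -> float:
        return self.genome_size_bp * self.mean_bp_mass / AVOGADRO

    def copies_per_uL(self, dilution: float) -> float:
        """16S gene copies per microlitre of a diluted standard."""
        mass_g = dilution * self.stock_ng_per_uL * 1e-9
        return mass_g / self.genome_mass_g() * self.gene_copies_per_genome


@dataclass
class QpcrResult:
    curve_slope: float
    curve_intercept: float
    curve_r2: float
    copies_per_g: pd.Series
    flags: pd.DataFrame  # per-sample: extrapolated, inhibited


def quantify_qpcr(
    ct_table: pd.DataFrame,
    standard: QpcrStandard | None = None,
    standard_table: pd.DataFrame | None = None,
    inhibition_shift_threshold: float = 1.0,
) -> QpcrResult:
    """Convert sample Ct values to 16S copies per gram wet sediment.

    ``standard_table`` needs columns ``dilution`` and ``ct``;
    ``ct_table`` needs ``sample``, ``ct``, ``template_dilution``,
    ``sediment_g``, ``elution_uL`` and optionally ``inhibition_shift``.
    The calibration is an OLS fit of Ct on log10(copies/uL); samples are
    interpolated on that line, then scaled by the template dilution and the
    extraction yield (elution volume over wet-sediment mass).
    """
    standard = standard or QpcrStandard()
    if standard_table is None:
        raise CommunityError("a measured standard table is required")
    log_copies = np.log10(
        [standard.copies_per_uL(d) for d in standard_table["dilution"]]
    )
    if len(np.unique(np.round(log_copies, 6))) < 3 or np.ptp(log_copies) < 2:
        raise CommunityError("standard series must span >=3 points over >=2 decades")
    slope, intercept, r, _, _ = stats.linregress(log_copies, standard_table["ct"])

    ct = ct_table.set_index("sample")
    sample_log_copies = (ct["ct"] - intercept) / slope
    per_uL = 10.0 ** sample_log_copies
    copies_per_g = (
        per_uL * ct["template_dilution"] * ct["elution_uL"] / ct["sediment_g"]
    )
    extrapolated = (sample_log_copies < log_copies.min()) | (
        sample_log_copies > log_copies.max()
    )
    if "inhibition_shift" in ct.columns:
        inhibited = ct["inhibition_shift"].abs() > inhibition_shift_threshold
    else:
        inhibited = pd.Series(False, index=ct.index)
    flags = pd.DataFrame({"extrapolated": extrapolated, "inhibited": inhibited})
    return QpcrResult(float(slope), float(intercept), float(r**2),
                      copies_per_g.rename("copies_per_g"), flags)


def absolute_guild_proxy(
    relabund: pd.DataFrame, copies_per_g: pd.Series, zones: pd.Series
) -> tuple[pd.DataFrame, list[GuildTestResult]]:
    """Guild relative abundance x total 16S copies: proxy absolute abundances.

    Unmatched samples are dropped with a warning.  Returns per-sample proxy
    abundances (copies per gram attributable to each guild) plus edge-vs-middle
    t/ANOVA contrasts.
    """
    shared = relabund.index.intersection(copies_per_g.index)
    missing = relabund.index.difference(shared)
    if len(missing):
        warnings.warn(f"dropping unmatched samples: {list(missing)}")
    if len(shared) == 0:
        raise CommunityError("no samples shared between abundances and qPCR")
    proxy = relabund.loc[shared].div(100.0).mul(copies_per_g.loc[shared], axis=0)
    tests: list[GuildTestResult] = []
    labels = zones.loc[shared]
    levels = sorted(labels.unique())
    if len(levels) == 2:
        a, b = levels
        for g in proxy.columns:
            xa = proxy.loc[labels == a, g]
            xb = proxy.loc[labels == b, g]
            t, tp = stats.ttest_ind(xa, xb)
            F, fp = stats.f_oneway(xa, xb)
            tests.append(GuildTestResult(g, float(t), float(tp), float(F), float(fp)))
    return proxy, tests
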