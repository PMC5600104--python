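"""GWAS summary statistics: parsing, allele harmonization, LD pruning, model subsets.

A Mendelian-randomization instrument is assembled from two per-SNP summary
association tables — one for the exposure (cups of coffee per day), one for
the outcome (cigarettes per day, or SD units of plasma cotinine).  Before the
per-SNP effects can be combined into a causal estimate the two sources must
refer to the same effect allele at every SNP (harmonization), the SNPs must be
mutually independent (LD pruning), and the instrument may be restricted to a
named sub-model of SNPs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = (frozenset("AT"), frozenset("CG"))

#: SNP membership of the three named instrument models for coffee consumption.
#: The 6-SNP model drops the two variants with the weakest replication-stage
#: exposure evidence; the 2-SNP model keeps only the caffeine-metabolism loci
#: (AHR, CYP1A1).
MODEL_SNPS: dict[str, tuple[str, ...]] = {
    "8-SNP": (
        "rs1260326", "rs1481012", "rs4410790", "rs7800944",
        "rs17685", "rs6265", "rs2470893", "rs9902453",
    ),
    "6-SNP": (
        "rs1260326", "rs4410790", "rs7800944",
        "rs17685", "rs2470893", "rs9902453",
    ),
    "2-SNP": ("rs4410790", "rs2470893"),
}

REQUIRED_COLUMNS = ("snp_id", "gene", "effect_allele", "other_allele", "beta", "se")


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-phenotype summary statistic.

    ``beta`` is the per-effect-allele change in the phenotype (cups/day for the
    exposure; cigarettes/day or SD-cotinine for the outcome) and ``se`` its
    standard error in the same units.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    phenotype: str = "exposure"
    gene_label: str | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be one of A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta must be finite")

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return VariantAssociation(
            snp_id=self.snp_id,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            se=self.se,
            phenotype=self.phenotype,
            gene_label=self.gene_label,
            n=self.n,
        )


@dataclass(frozen=True)
class InstrumentPair:
    """Harmonized exposure/outcome effect pair for one SNP (shared effect allele)."""

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")


@dataclass
class InstrumentSet:
    """A harmonized, analysis-ready MR instrument.

    ``ld_r2``, when provided, maps frozenset pairs of snp_ids to pairwise r².
    """

    entries: list[InstrumentPair]
    model_label: str = "custom"
    ld_r2: Mapping[frozenset, float] | None = None

    def __post_init__(self) -> None:
        ids = [e.snp_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate snp_id in instrument set")

    @property
    def snp_ids(self) -> list[str]:
        return [e.snp_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, snp_ids: Iterable[str], model_label: str = "custom") -> "InstrumentSet":
        wanted = set(snp_ids)
        return InstrumentSet(
            entries=[e for e in self.entries if e.snp_id in wanted],
            model_label=model_label,
            ld_r2=self.ld_r2,
        )

    def to_json(self) -> str:
        doc = {
            "model_label": self.model_label,
            "entries": [
                {"snp_id": e.snp_id, "beta_x": e.beta_x, "se_x": e.se_x,
                 "beta_y": e.beta_y, "se_y": e.se_y}
                for e in self.entries
            ],
            "provenance": {"format": "mrkinetics.InstrumentSet", "version": 1},
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "InstrumentSet":
        doc = json.loads(text)
        entries = [InstrumentPair(**e) for e in doc["entries"]]
        return cls(entries=entries, model_label=doc.get("model_label", "custom"))


def parse_summary_table(source, phenotype: str = "exposure") -> list[VariantAssociation]:
    """Read a tab-separated summary-statistics table into VariantAssociations.

    Required columns: ``snp_id  gene  effect_allele  other_allele  beta  se``
    (header row required; extra columns ignored).  Rows are returned in file
    order at full parsed precision.

    Parameters
    ----------
    source : path or file-like
        TSV input.
    phenotype : {"exposure", "outcome"}
        Tag recorded on each returned association.
    """
    if phenotype not in ("exposure", "outcome"):
        raise ValidationError(f"phenotype must be 'exposure' or 'outcome', got {phenotype!r}")
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not read summary table: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"summary table missing required column(s): {', '.join(missing)}")

    out: list[VariantAssociation] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        snp = str(row["snp_id"]).strip()
        if snp in seen:
            raise ValidationError(f"duplicate snp_id {snp!r} at row {i}")
        seen.add(snp)
        try:
            beta = float(row["beta"])
            se = float(row["se"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i} ({snp}): non-numeric beta/se") from exc
        try:
            out.append(
                VariantAssociation(
                    snp_id=snp,
                    gene_label=str(row["gene"]).strip() or None,
                    effect_allele=str(row["effect_allele"]).strip().upper(),
                    other_allele=str(row["other_allele"]).strip().upper(),
                    beta=beta,
                    se=se,
                    phenotype=phenotype,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return out


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_policy: str = "strict",
) -> InstrumentSet:
    """Pair exposure and outcome associations on a shared effect allele.

    For every exposure SNP the outcome table must contain the same SNP.  If the
    two sources report the same effect/other alleles the pair is taken as-is;
    if the labels are swapped the outcome beta sign is flipped.  Irreconcilable
    allele pairs raise :class:`HarmonizationError`.  Palindromic SNPs (A/T or
    C/G) are ambiguous with respect to strand; under the default ``"strict"``
    policy they are rejected, under ``"allow"`` both sources are assumed to be
    on the same strand.  Outcome SNPs absent from the exposure table are
    ignored (logged).
    """
    if palindromic_policy not in ("strict", "allow"):
        raise ValidationError(f"unknown palindromic policy {palindromic_policy!r}")
    by_id = {v.snp_id: v for v in outcome}
    extra = set(by_id) - {v.snp_id for v in exposure}
    if extra:
        logger.info("ignoring %d outcome-only SNP(s): %s", len(extra), sorted(extra))

    pairs: list[InstrumentPair] = []
    for exp in exposure:
        if exp.snp_id not in by_id:
            raise HarmonizationError(f"{exp.snp_id}: missing from outcome table")
        out = by_id[exp.snp_id]
        if exp.is_palindromic or out.is_palindromic:
            if palindromic_policy == "strict":
                raise HarmonizationError(
                    f"{exp.snp_id}: palindromic alleles "
                    f"({exp.effect_allele}/{exp.other_allele}) rejected under strict policy"
                )
        if (exp.effect_allele, exp.other_allele) == (out.effect_allele, out.other_allele):
            harmonized = out
        elif (exp.effect_allele, exp.other_allele) == (out.other_allele, out.effect_allele):
            harmonized = out.flipped()
            logger.info("%s: outcome alleles swapped; beta sign flipped", exp.snp_id)
        else:
            raise HarmonizationError(
                f"{exp.snp_id}: irreconcilable alleles "
                f"exposure {exp.effect_allele}/{exp.other_allele} vs "
                f"outcome {out.effect_allele}/{out.other_allele}"
            )
        pairs.append(
            InstrumentPair(
                snp_id=exp.snp_id,
                beta_x=exp.beta, se_x=exp.se,
                beta_y=harmonized.beta, se_y=harmonized.se,
            )
        )
    return InstrumentSet(entries=pairs)


def ld_prune(instrument_set: InstrumentSet, threshold: float, seed: int) -> InstrumentSet:
    """Remove SNPs until all pairwise LD r² fall below ``threshold``.

    Within each offending pair, one of the two SNPs is removed uniformly at
    random under ``seed``; iteration is over sorted snp_id pairs so the random
    stream (and hence the retained set) is reproducible.
    """
    if not (0 < threshold <= 1):
        raise ValidationError(f"threshold must be in (0, 1], got {threshold}")
    if instrument_set.ld_r2 is None:
        raise ValidationError("instrument set carries no LD r² matrix")
    r2 = instrument_set.ld_r2
    ids = sorted(instrument_set.snp_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if frozenset((a, b)) not in r2:
                raise ValidationError(f"missing LD r² for pair ({a}, {b})")

    rng = np.random.default_rng(seed)
    keep = set(ids)
    # repeatedly drop one member of the worst-offending sorted pair
    changed = True
    while changed:
        changed = False
        kept_sorted = sorted(keep)
        for i, a in enumerate(kept_sorted):
            for b in kept_sorted[i + 1:]:
                if r2[frozenset((a, b))] >= threshold:
                    victim = a if rng.random() < 0.5 else b
                    keep.discard(victim)
                    logger.info("LD prune: removed %s (pair %s/%s, r2=%.4g)",
                                victim, a, b, r2[frozenset((a, b))])
                    changed = True
                    break
            if changed:
                break
    return instrument_set.subset(keep, model_label=instrument_set.model_label)


def select_model(instrument_set: InstrumentSet, model_label: str) -> InstrumentSet:
    """Restrict an instrument set to one of the named coffee-consumption models."""
    if model_label not in MODEL_SNPS:
        raise ValidationError(
            f"unknown model {model_label!r}; expected one of {sorted(MODEL_SNPS)}"
        )
    wanted = MODEL_SNPS[model_label]
    have = set(instrument_set.snp_ids)
    missing = [s for s in wanted if s not in have]
    if missing:
        raise ValidationError(
            f"model {model_label} requires SNP(s) absent from the set: {', '.join(missing)}"
        )
    sub = instrument_set.subset(wanted, model_label=model_label)
    # preserve the canonical model ordering
    order = {s: i for i, s in enumerate(wanted)}
    sub.entries.sort(key=lambda e: order[e.snp_id])
    return sub
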