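"""Deterministic PPI dosing rules engine for stress ulcer prophylaxis.

Maps (predictive phenotype, clinical context) to a dosing recommendation.
The rules themselves live in a declarative, versioned YAML table
(``rules/sup_rules.yaml``) evaluated top-down, first match wins; the engine
is a small interpreter, so the guideline content can evolve without code
changes. Dose adjustments are expressed as multiplier intervals relative to
the drug's standard daily dose for SUP (e.g. "increase by 50-100%" is
[1.5, 2.0]); :func:`absolute_dose` converts them to mg/day.

Priorities encoded in the table, highest first: PPI hypersensitivity (switch
to a non-PPI agent — H2 receptor antagonist or gastric mucosa protectant);
missing genotype, unknown phenotype or interacting co-medication
(CYP2C19-independent therapy, i.e. rabeprazole); rabeprazole suits all
metabolizer groups; then phenotype- and indication-specific adjustments.
Ambivalent metabolizers (AM) are dosed with the reduced-function group but
every AM recommendation is flagged provisional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from importlib import resources
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .calling import CohortCallResult, Phenotype, PredictivePhenotype
from .errors import StandardDoseUnavailableError, VocabularyError


class Drug(str, Enum):
    OMEPRAZOLE = "omeprazole"
    ESOMEPRAZOLE = "esomeprazole"
    LANSOPRAZOLE = "lansoprazole"
    PANTOPRAZOLE = "pantoprazole"
    RABEPRAZOLE = "rabeprazole"
    DEXLANSOPRAZOLE = "dexlansoprazole"


class Indication(str, Enum):
    SUP = "SUP"
    H_PYLORI_ERADICATION = "H_PYLORI_ERADICATION"
    EROSIVE_ESOPHAGITIS = "EROSIVE_ESOPHAGITIS"


class Action(str, Enum):
    STANDARD_DOSE = "STANDARD_DOSE"
    INCREASE = "INCREASE"
    REDUCE_CONSIDER = "REDUCE_CONSIDER"
    SWITCH_AGENT = "SWITCH_AGENT"
    NO_SPECIFIC_RECOMMENDATION = "NO_SPECIFIC_RECOMMENDATION"


#: First-generation PPIs; dexlansoprazole inherits their rules by
#: extrapolation from lansoprazole.
FIRST_GENERATION = frozenset(
    {Drug.OMEPRAZOLE, Drug.LANSOPRAZOLE, Drug.PANTOPRAZOLE})

#: Non-PPI agent classes usable for SUP when PPIs are contraindicated.
NON_PPI_AGENTS = "H2RA/GMP"

_PREFERRED_AGENT_VOCAB = {d.value for d in Drug} | {NON_PPI_AGENTS}


@dataclass(frozen=True)
class StandardDose:
    """Reference standard daily dose for SUP."""

    drug: Drug
    dose_mg_per_day: float
    duration_note: str


#: Standard SUP doses. Dexlansoprazole has no published standard SUP dose,
#: so its recommendations stay text-only (see absolute_dose).
STANDARD_DOSES: Mapping[Drug, StandardDose] = {
    Drug.OMEPRAZOLE: StandardDose(Drug.OMEPRAZOLE, 20.0, "4-8 weeks"),
    Drug.LANSOPRAZOLE: StandardDose(Drug.LANSOPRAZOLE, 30.0, "8 weeks"),
    Drug.PANTOPRAZOLE: StandardDose(Drug.PANTOPRAZOLE, 20.0, "4-8 weeks"),
    Drug.ESOMEPRAZOLE: StandardDose(Drug.ESOMEPRAZOLE, 20.0, "4-8 weeks"),
    Drug.RABEPRAZOLE: StandardDose(Drug.RABEPRAZOLE, 20.0, "4-8 weeks"),
}


def _coerce(enum_cls, value, what: str):
    try:
        return enum_cls(value)
    except ValueError as exc:
        raise VocabularyError(
            f"unknown {what} {value!r}; expected one of "
            f"{[e.value for e in enum_cls]}") from exc


@dataclass(frozen=True)
class ClinicalContext:
    """Patient/therapy context consumed by the rules engine."""

    drug: Drug
    indication: Indication = Indication.SUP
    chronic_over_12_weeks: bool = False
    h_pylori_positive: bool = False
    ppi_hypersensitivity: bool = False
    genotype_available: bool = True
    interacting_cyp_drug: bool = False

    def __post_init__(self):
        object.__setattr__(self, "drug", _coerce(Drug, self.drug, "drug"))
        object.__setattr__(
            self, "indication",
            _coerce(Indication, self.indication, "indication"))


@dataclass(frozen=True)
class Recommendation:
    """Dosing action with multiplier range, preferred agent and rationale."""

    action: Action
    multiplier_low: float
    multiplier_high: float
    preferred_agent: str | None
    split_dose_allowed: bool
    rationale: str
    provisional: bool
    rule_id: str

    def __post_init__(self):
        if not (0 <= self.multiplier_low <= self.multiplier_high):
            raise ValueError("multipliers must satisfy 0 <= low <= high")
        if self.action is Action.STANDARD_DOSE and not (
                self.multiplier_low == self.multiplier_high == 1.0):
            raise ValueError("STANDARD_DOSE implies multipliers of 1.0")
        if not self.rationale.strip():
            raise ValueError("rationale must be non-empty")
        if (self.preferred_agent is not None
                and self.preferred_agent not in _PREFERRED_AGENT_VOCAB):
            raise VocabularyError(
                f"unknown preferred agent {self.preferred_agent!r}")


@dataclass(frozen=True)
class Rule:
    """One row of the declarative rule table."""

    rule_id: str
    when: Mapping[str, Any]
    action: Action
    multiplier_low: float
    multiplier_high: float
    preferred_agent: str | None
    split_dose_allowed: bool
    rationale: str

    _FLAG_KEYS = ("chronic_over_12_weeks", "h_pylori_positive",
                  "ppi_hypersensitivity", "genotype_available",
                  "interacting_cyp_drug")

    def matches(self, phenotype: Phenotype, ctx: ClinicalContext) -> bool:
        for key, want in self.when.items():
            if key == "phenotype":
                have = phenotype.value
            elif key == "drug":
                have = ctx.drug.value
            elif key == "indication":
                have = ctx.indication.value
            elif key in self._FLAG_KEYS:
                if getattr(ctx, key) != bool(want):
                    return False
                continue
            else:
                raise VocabularyError(
                    f"rule {self.rule_id}: unknown predicate field {key!r}")
            allowed = want if isinstance(want, list) else [want]
            if have not in allowed:
                return False
        return True


class RuleTable:
    """Ordered rule set loaded from YAML; first matching rule fires."""

    def __init__(self, rules: Sequence[Rule], version: str):
        self.rules = list(rules)
        self.version = version
        ids = [r.rule_id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise VocabularyError("duplicate rule ids in rule table")

    @classmethod
    def from_yaml(cls, text: str) -> "RuleTable":
        doc = yaml.safe_load(text)
        rules = []
        for raw in doc["rules"]:
            lo, hi = raw["multiplier"]
            rules.append(Rule(
                rule_id=raw["id"],
                when=raw.get("when", {}),
                action=_coerce(Action, raw["action"], "action"),
                multiplier_low=float(lo),
                multiplier_high=float(hi),
                preferred_agent=raw.get("preferred_agent"),
                split_dose_allowed=bool(raw.get("split_dose_allowed", False)),
                rationale=str(raw["rationale"]).strip(),
            ))
        return cls(rules, version=str(doc["version"]))

    @classmethod
    def default(cls) -> "RuleTable":
        text = (resources.files("cyp2c19sup") / "rules" / "sup_rules.yaml"
                ).read_text(encoding="utf-8")
        return cls.from_yaml(text)

    def rationale_by_id(self) -> dict[str, str]:
        return {r.rule_id: r.rationale for r in self.rules}


_DEFAULT_TABLE: RuleTable | None = None


def default_rule_table() -> RuleTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = RuleTable.default()
    return _DEFAULT_TABLE


def recommend(phenotype: PredictivePhenotype, ctx: ClinicalContext,
              table: RuleTable | None = None) -> Recommendation:
    """Return the dosing recommendation for one phenotype/context pair.

    Deterministic and total over the finite phenotype × drug × indication ×
    flag space; exactly one rule fires per call.
    """
    table = table or default_rule_table()
    for rule in table.rules:
        if rule.matches(phenotype.label, ctx):
            return Recommendation(
                action=rule.action,
                multiplier_low=rule.multiplier_low,
                multiplier_high=rule.multiplier_high,
                preferred_agent=rule.preferred_agent,
                split_dose_allowed=rule.split_dose_allowed,
                rationale=rule.rationale,
                provisional=phenotype.provisional,
                rule_id=rule.rule_id,
            )
    raise VocabularyError(  # unreachable with the shipped table
        f"no rule matched phenotype={phenotype.label.value} ctx={ctx}")


def absolute_dose(rec: Recommendation, drug: Drug | str) -> tuple[float, float]:
    """Convert a recommendation's multiplier range to mg/day for ``drug``."""
    drug = _coerce(Drug, drug, "drug")
    std = STANDARD_DOSES.get(drug)
    if std is None:
        raise StandardDoseUnavailableError(
            f"no standard SUP dose is defined for {drug.value}; the "
            "recommendation is text-only")
    return (std.dose_mg_per_day * rec.multiplier_low,
            std.dose_mg_per_day * rec.multiplier_high)


@dataclass
class RecommendationReport:
    """Per-sample recommendations in machine- and human-readable forms."""

    rows: list[dict]
    rule_table_version: str

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {"rule_table_version": self.rule_table_version,
             "recommendations": self.rows}, indent=indent)

    def to_text(self) -> str:
        lines = [f"rule table version {self.rule_table_version}"]
        for r in self.rows:
            dose = ""
            if r["dose_mg_per_day_low"] is not None:
                lo, hi = r["dose_mg_per_day_low"], r["dose_mg_per_day_high"]
                dose = (f" [{lo:g} mg/day]" if lo == hi
                        else f" [{lo:g}-{hi:g} mg/day]")
            pref = (f" -> prefer {r['preferred_agent']}"
                    if r["preferred_agent"] else "")
            flag = " (provisional)" if r["provisional"] else ""
            lines.append(
                f"{r['sample_id']}\t{r['phenotype']}\t{r['drug']}\t"
                f"{r['action']}{dose}{pref}{flag}\t[{r['rule_id']}]")
        return "\n".join(lines) + "\n"


def recommendation_report(
    calls: CohortCallResult,
    ctx: ClinicalContext,
    table: RuleTable | None = None,
) -> RecommendationReport:
    """Build one recommendation row per sample of a cohort call result.

    Uncallable samples (missing genotype slot) are included with
    ``genotype_available=False``, which routes them to CYP2C19-independent
    therapy rather than dropping them.
    """
    table = table or default_rule_table()
    rows: list[dict] = []

    def _row(sample_id: str, haplogenotype: str | None,
             phenotype: PredictivePhenotype, row_ctx: ClinicalContext,
             status: str) -> dict:
        rec = recommend(phenotype, row_ctx, table)
        try:
            lo, hi = absolute_dose(rec, row_ctx.drug)
        except StandardDoseUnavailableError:
            lo = hi = None
        return {
            "sample_id": sample_id,
            "status": status,
            "haplogenotype": haplogenotype,
            "phenotype": phenotype.label.value,
            "drug": row_ctx.drug.value,
            "indication": row_ctx.indication.value,
            "action": rec.action.value,
            "multiplier_low": rec.multiplier_low,
            "multiplier_high": rec.multiplier_high,
            "dose_mg_per_day_low": lo,
            "dose_mg_per_day_high": hi,
            "preferred_agent": rec.preferred_agent,
            "split_dose_allowed": rec.split_dose_allowed,
            "provisional": rec.provisional,
            "rule_id": rec.rule_id,
            "rationale": rec.rationale,
        }

    for rec_row in calls.table.itertuples(index=False):
        phenotype = PredictivePhenotype(
            Phenotype(rec_row.phenotype),
            provisional=bool(rec_row.provisional))
        rows.append(_row(rec_row.sample_id, rec_row.haplogenotype,
                         phenotype, ctx, status="called"))
    for sample_id in calls.uncallable:
        no_geno = ClinicalContext(
            drug=ctx.drug, indication=ctx.indication,
            chronic_over_12_weeks=ctx.chronic_over_12_weeks,
            h_pylori_positive=ctx.h_pylori_positive,
            ppi_hypersensitivity=ctx.ppi_hypersensitivity,
            genotype_available=False,
            interacting_cyp_drug=ctx.interacting_cyp_drug)
        rows.append(_row(sample_id, None,
                         PredictivePhenotype(Phenotype.UNKNOWN),
                         no_geno, status="uncallable"))
    return RecommendationReport(rows=rows, rule_table_version=table.version)
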