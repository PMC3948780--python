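"""Decision rules mapping statistical outcomes to recruitment hypotheses.

The framework distinguishes seven mechanisms that can limit shrub
recruitment in a patchy dryland landscape:

========================  ====================================================
verdict key               mechanism
========================  ====================================================
``SL_DIS``                distance seed limitation (seeds confined to shadows)
``SL_DEN``                density seed limitation (too few seeds locally)
``HP_AL_SS``              small-scale allogenic habitat patchiness
``HP_AL_LS_STAT``         static large-scale allogenic habitat patchiness
``HP_AL_LS_DYN``          dynamic large-scale allogenic habitat patchiness
``HP_AU_FA``              autogenic facilitation by large adults
``HP_AU_CO``              autogenic competition from large adults
========================  ====================================================

Decision rules (all evidence at the levels fixed upstream: correlations at
p < 0.05, envelope GoF at the 0.01 per-tail rank rule):

* ``SL_DIS`` = y iff the adult-FVC vs recruit-density correlation (Corr1)
  is significant at either plot size.
* ``SL_DEN`` and ``HP_AL_SS`` = y iff isolated unbranched individuals
  occur; pattern analysis alone cannot separate the two (seed-addition
  experiments would be needed), so both carry a shared caveat flag.
* Large-scale allogenic HP is present iff at least one cohort's PCF lies
  significantly above its null envelope at cluster scales > 10 m; given
  presence, the static/dynamic split follows the cohort-density
  correlation count (Corr2) — the two verdicts are mutually exclusive.
* ``HP_AU_CO`` (``HP_AU_FA``) = y iff any cohort's PCCF against the large
  adults falls significantly below (above) its bivariate null envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .envelopes import DeviationInterval
from .geometry import COHORTS
from .gridstats import DistanceSLResult, StaticDynamicResult

__all__ = [
    "PCFVerdict",
    "EvidenceBundle",
    "HypothesisReport",
    "evaluate_framework",
    "HYPOTHESES",
]

HYPOTHESES: tuple[str, ...] = (
    "SL_DIS",
    "SL_DEN",
    "HP_AL_SS",
    "HP_AL_LS_STAT",
    "HP_AL_LS_DYN",
    "HP_AU_FA",
    "HP_AU_CO",
)

#: caveat attached to the two verdicts pattern analysis cannot separate
SHARED_CAVEAT = (
    "density seed limitation and small-scale allogenic habitat patchiness "
    "are not separable by pattern analysis alone; seed-addition experiments "
    "would be required"
)

LARGE_SCALE_THRESHOLD_M = 10.0


@dataclass(frozen=True)
class PCFVerdict:
    """Univariate PCF outcome for one cohort."""

    direction: str  # "above" | "below" | "none"
    cluster_scale: float | None = None


@dataclass
class EvidenceBundle:
    """All statistical inputs the decision tree consumes."""

    iso_ui: bool
    pcf_verdicts: Mapping[str, PCFVerdict]
    pccf_verdicts: Mapping[str, Sequence[DeviationInterval]]  # cohort vs A_L
    corr1: DistanceSLResult
    corr2: StaticDynamicResult

    def missing_fields(self) -> list[str]:
        missing = [c for c in COHORTS if c not in self.pcf_verdicts]
        if "A_L" in self.pccf_verdicts:
            missing.append("pccf_verdicts must exclude A_L vs A_L")
        return missing


@dataclass
class HypothesisReport:
    """Per-hypothesis y/n verdicts with their evidence trail."""

    verdicts: dict[str, str]  # hypothesis -> "y" | "n"
    evidence: dict[str, str] = field(default_factory=dict)
    caveats: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> tuple[str, ...]:
        return tuple(self.verdicts[h] for h in HYPOTHESES)

    def to_markdown(self) -> str:
        head = "| " + " | ".join(HYPOTHESES) + " |"
        rule = "|" + "---|" * len(HYPOTHESES)
        row = "| " + " | ".join(self.as_row()) + " |"
        return "\n".join([head, rule, row])


def evaluate_framework(evidence: EvidenceBundle) -> HypothesisReport:
    """Apply the decision tree to a complete evidence bundle."""
    missing = evidence.missing_fields()
    if missing:
        raise ValueError(f"incomplete evidence bundle: {missing}")

    verdicts: dict[str, str] = {}
    why: dict[str, str] = {}
    caveats: dict[str, str] = {}

    corr1_sig = evidence.corr1.verdict == "supported"
    verdicts["SL_DIS"] = "y" if corr1_sig else "n"
    why["SL_DIS"] = (
        "adult FVC correlates with recruit density"
        if corr1_sig
        else "no significant adult-FVC vs recruit-density correlation"
    )

    iso = bool(evidence.iso_ui)
    for h in ("SL_DEN", "HP_AL_SS"):
        verdicts[h] = "y" if iso else "n"
        why[h] = (
            "isolated unbranched individuals occur"
            if iso
            else "no isolated unbranched individuals"
        )
        caveats[h] = SHARED_CAVEAT

    ls_cohorts = [
        c
        for c, v in evidence.pcf_verdicts.items()
        if v.direction == "above"
        and v.cluster_scale is not None
        and v.cluster_scale > LARGE_SCALE_THRESHOLD_M
    ]
    ls_present = bool(ls_cohorts)
    if ls_present:
        dynamic = evidence.corr2.verdict == "dynamic"
        verdicts["HP_AL_LS_DYN"] = "y" if dynamic else "n"
        verdicts["HP_AL_LS_STAT"] = "n" if dynamic else "y"
        why["HP_AL_LS_DYN"] = why["HP_AL_LS_STAT"] = (
            f"cohorts {ls_cohorts} cluster at > {LARGE_SCALE_THRESHOLD_M:g} m; "
            f"{evidence.corr2.n_significant}/{evidence.corr2.n_pairs} cohort-pair "
            f"density correlations significant -> {evidence.corr2.verdict}"
        )
    else:
        verdicts["HP_AL_LS_DYN"] = verdicts["HP_AL_LS_STAT"] = "n"
        why["HP_AL_LS_DYN"] = why["HP_AL_LS_STAT"] = (
            "no cohort PCF significantly above its envelope at large scales"
        )

    above = [
        c
        for c, ivs in evidence.pccf_verdicts.items()
        for iv in ivs
        if iv.significant and iv.sign == "above"
    ]
    below = [
        c
        for c, ivs in evidence.pccf_verdicts.items()
        for iv in ivs
        if iv.significant and iv.sign == "below"
    ]
    verdicts["HP_AU_FA"] = "y" if above else "n"
    verdicts["HP_AU_CO"] = "y" if below else "n"
    why["HP_AU_FA"] = (
        f"PCCF vs large adults significantly above envelope for {sorted(set(above))}"
        if above
        else "no PCCF significantly above its bivariate envelope"
    )
    why["HP_AU_CO"] = (
        f"PCCF vs large adults significantly below envelope for {sorted(set(below))}"
        if below
        else "no PCCF significantly below its bivariate envelope"
    )

    return HypothesisReport(verdicts, why, caveats)
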