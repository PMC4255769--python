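"""Deletion-bin label parsing and reconciliation with shotgun arm calls.

Wheat deletion bins are chromosomal intervals defined by terminal-deletion
stocks and labelled by arm and fraction length, e.g. ``C-1AS1-0.47`` (the
interval from the centromere to 47% of 1AS) or ``1AL1-0.17-0.61``.  Labels
beginning with ``C-`` are centromere-anchored.

A deletion-bin EST location is reconciled against a chromosome-arm call
from shotgun data as follows: same arm is *concordant*; a different arm is
*contradicts*, unless the bin is centromere-anchored and no ditelosomic
hybridization evidence distinguishes the arms, in which case the bin is
*uninformative_pericentromeric* -- a pericentromeric bin location is
concluded when a fragment is present in all deletion lines, which by itself
does not differentiate a pericentromeric short-arm from long-arm location.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import FormatError, ValidationError

VERDICT_CONCORDANT = "concordant"
VERDICT_CONTRADICTS = "contradicts"
VERDICT_UNINFORMATIVE = "uninformative_pericentromeric"

#: Frozen column order of the verdict TSV.
VERDICT_COLUMNS = ["est_id", "bin_label", "arm_call", "verdict", "note"]

# Both plain hyphen and en-dash occur as interval separators in the wild.
_LABEL_RE = re.compile(
    r"""^(?P<anchored>C-)?
        (?P<group>[1-7])(?P<subgenome>[ABD])(?P<arm>[SL])
        -?(?P<bin>\d+)?
        -(?P<f1>\d+(?:\.\d+)?)
        (?:[-–](?P<f2>\d+(?:\.\d+)?))?$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class DeletionBinLocus:
    """A parsed deletion-bin location label."""

    label: str
    chromosome: str
    arm: str
    centromere_anchored: bool
    lo: float
    hi: float
    est_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 1):
            raise ValidationError(
                f"bin fraction interval must satisfy 0 <= lo < hi <= 1, got "
                f"[{self.lo}, {self.hi}] in {self.label!r}"
            )


def parse_bin_label(label: str, est_id: str | None = None) -> DeletionBinLocus:
    """Parse a deletion-bin label such as 'C-1AS1-0.47' or '1AL1-0.17-0.61'.

    Centromere-anchored labels ('C-' prefix) carry a single fraction f and
    denote the interval [0, f] measured from the centromere outward; other
    labels carry an explicit fraction interval.
    """
    if not label:
        raise FormatError("empty deletion-bin label")
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise FormatError(f"unparseable deletion-bin label: {label!r}")
    anchored = m.group("anchored") is not None
    f1 = float(m.group("f1"))
    f2 = m.group("f2")
    if anchored:
        if f2 is not None:
            raise FormatError(
                f"centromere-anchored label must carry a single fraction: {label!r}"
            )
        lo, hi = 0.0, f1
    else:
        if f2 is None:
            raise FormatError(
                f"distal bin label requires a fraction interval: {label!r}"
            )
        lo, hi = f1, float(f2)
    return DeletionBinLocus(
        label=label,
        chromosome=f"{m.group('group')}{m.group('subgenome')}",
        arm=m.group("arm"),
        centromere_anchored=anchored,
        lo=lo,
        hi=hi,
        est_id=est_id,
    )


def reconcile(
    arm_call: str,
    bin_locus: DeletionBinLocus,
    ditelosomic_evidence: bool = True,
) -> tuple[str, str]:
    """Verdict for one (shotgun arm call, deletion-bin location) pair.

    `arm_call` is an arm name such as '4AL'.  Returns (verdict, note).
    """
    if len(arm_call) != 3:
        raise ValidationError(f"not an arm name: {arm_call!r}")
    call_chrom, call_arm = arm_call[:2], arm_call[2]
    if call_chrom != bin_locus.chromosome:
        raise ValidationError(
            f"chromosome mismatch: call on {call_chrom}, bin on {bin_locus.chromosome}"
        )
    if call_arm == bin_locus.arm:
        return VERDICT_CONCORDANT, "same arm"
    if bin_locus.centromere_anchored and not ditelosomic_evidence:
        return (
            VERDICT_UNINFORMATIVE,
            "centromere-anchored bin without ditelosomic arm evidence cannot "
            "distinguish pericentromeric short- from long-arm locations",
        )
    return VERDICT_CONTRADICTS, "opposite arm"


def reconcile_all(calls: pd.DataFrame, bins: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Join arm calls with deletion-bin locations and apply the decision rule.

    `calls` needs columns (est_id, arm_call); `bins` needs (est_id,
    bin_label) and optionally ditelosomic_evidence (default available).
    Returns one verdict row per joined pair plus summary counts.
    """
    for col in ("est_id", "arm_call"):
        if col not in calls.columns:
            raise ValidationError(f"calls table lacks column {col!r}")
    for col in ("est_id", "bin_label"):
        if col not in bins.columns:
            raise ValidationError(f"bins table lacks column {col!r}")
    bins = bins.copy()
    if "ditelosomic_evidence" not in bins.columns:
        bins["ditelosomic_evidence"] = True

    joined = calls.merge(bins, on="est_id", how="inner")
    rows = []
    for rec in joined.itertuples(index=False):
        locus = parse_bin_label(rec.bin_label, est_id=rec.est_id)
        verdict, note = reconcile(rec.arm_call, locus, bool(rec.ditelosomic_evidence))
        rows.append(
            {
                "est_id": rec.est_id,
                "bin_label": rec.bin_label,
                "arm_call": rec.arm_call,
                "verdict": verdict,
                "note": note,
            }
        )
    verdicts = pd.DataFrame(rows, columns=VERDICT_COLUMNS)
    summary = {v: 0 for v in (VERDICT_CONCORDANT, VERDICT_CONTRADICTS, VERDICT_UNINFORMATIVE)}
    if not verdicts.empty:
        summary.update(verdicts["verdict"].value_counts().to_dict())
    summary["n_pairs"] = len(verdicts)
    return verdicts, summary
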