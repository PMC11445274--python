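"""Summary counts of the clinical reference cohort, with recomputed shares.

The pipeline targets the suspected-recurrence glioblastoma setting studied
in a 61-patient (66-case) single-center cohort whose characteristics table
is public even though the images are not. The raw counts below are inputs;
the percentage shares and totals printed alongside them are *recomputed*
here and serve as exact worked examples for the bookkeeping used throughout
the package (class balance of supervoxels, case-level outcome mix, and the
outcome-by-MGMT-methylation contingency).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReferenceCohort:
    """Raw counts from the reference cohort characteristics table."""

    n_patients: int = 61
    n_cases: int = 66
    n_repeat_patients: int = 5

    # supervoxel-level response labels
    supervoxels_tp: int = 1069
    supervoxels_psp: int = 1128

    # case-level expert consensus at follow-up
    cases_tp: int = 37
    cases_psp: int = 12
    cases_mixed: int = 17

    # case outcome by MGMT promoter methylation status
    mgmt_methylated: tuple[int, int, int] = (15, 7, 11)  # TP, PsP, mixed
    mgmt_unmethylated: tuple[int, int, int] = (21, 4, 4)
    mgmt_unavailable: int = 4


REFERENCE = ReferenceCohort()


def _shares(counts: tuple[int, ...]) -> tuple[int, list[float]]:
    total = sum(counts)
    return total, [100.0 * c / total for c in counts]


def supervoxel_class_balance(
    cohort: ReferenceCohort = REFERENCE,
) -> dict[str, float]:
    """Total supervoxel count and TP/PsP percentage shares."""
    total, (tp_pct, psp_pct) = _shares(
        (cohort.supervoxels_tp, cohort.supervoxels_psp)
    )
    return {"total": total, "tp_pct": tp_pct, "psp_pct": psp_pct}


def case_outcome_distribution(
    cohort: ReferenceCohort = REFERENCE,
) -> dict[str, float]:
    """Case-level TP / PsP / mixed-response shares over all cases."""
    total, (tp, psp, mixed) = _shares(
        (cohort.cases_tp, cohort.cases_psp, cohort.cases_mixed)
    )
    return {
        "total": total,
        "tp_pct": tp,
        "psp_pct": psp,
        "mixed_pct": mixed,
    }


def mgmt_contingency(cohort: ReferenceCohort = REFERENCE) -> dict[str, dict]:
    """Outcome shares within MGMT methylated and unmethylated cases.

    Also recomputes the marginal split of cases by methylation status;
    the TP share is expected to be markedly higher in unmethylated tumors.
    """
    out: dict[str, dict] = {}
    for name, counts in (
        ("methylated", cohort.mgmt_methylated),
        ("unmethylated", cohort.mgmt_unmethylated),
    ):
        total, (tp, psp, mixed) = _shares(counts)
        out[name] = {
            "total": total,
            "tp_pct": tp,
            "psp_pct": psp,
            "mixed_pct": mixed,
        }
    n_meth = sum(cohort.mgmt_methylated)
    n_unmeth = sum(cohort.mgmt_unmethylated)
    status_total = n_meth + n_unmeth + cohort.mgmt_unavailable
    out["status_marginal"] = {
        "total": status_total,
        "methylated_pct": 100.0 * n_meth / status_total,
        "unmethylated_pct": 100.0 * n_unmeth / status_total,
        "unavailable_pct": 100.0 * cohort.mgmt_unavailable / status_total,
    }
    return out
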