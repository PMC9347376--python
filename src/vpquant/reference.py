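"""Published CVA21 (Coxsackievirus A21, V937) reference constants.

Sequence-calculated average masses and LC/MS-observed masses of the five
virion proteins, the adduct deltas used for intact-mass assignment, and the
reference retention times of the validated RP-UPLC method. These are
instrument/product facts consumed as constants.

The per-VP tryptophan counts used by the synthetic-data generator are NOT
published for CVA21; the values here are synthetic fixtures chosen to honor
the structural constraints the method relies on (VP4 carries no tryptophan,
and Trp is conserved across the VP0 -> VP2 + VP4 cleavage). Absolute values
are free parameters of the simulator, not properties of the virus.
"""

from __future__ import annotations

from .models import Adduct, ProteinSpecies, VPDefinition

#: Average molecular masses (Da) calculated from the VP amino-acid sequences.
CALC_MASS = {
    "VP0": 37_183.0,
    "VP1": 33_231.0,
    "VP2": 29_897.0,
    "VP3": 26_546.0,
    "VP4": 7_304.0,
}

#: Intact masses (Da) observed on LC/MS for the five VP peaks.
OBSERVED_MASS = {
    "VP0": 37_418.0,
    "VP1": 33_230.0,
    "VP2": 29_922.0,
    "VP3": 26_591.0,
    "VP4": 7_516.0,
}

#: Published peak assignments for the observed masses (species + adducts).
OBSERVED_ASSIGNMENT = {
    "VP0": ("VP0", (("Myr", 1), ("Na", 1))),
    "VP1": ("VP1", ()),
    "VP2": ("VP2", (("Na", 1),)),
    "VP3": ("VP3", (("Na", 2),)),
    "VP4": ("VP4", (("Myr", 1),)),
}

#: Myristoylation: C14 fatty-acyl chain, average mass shift.
MYR_DELTA = 210.36
#: Sodium adduct as H->Na replacement on the neutral mass.
NA_DELTA = 21.98

DEFAULT_ADDUCTS = (
    Adduct("Myr", MYR_DELTA, max_count=1),
    Adduct("Na", NA_DELTA, max_count=3),
)

#: Mass-assignment tolerance (Da); published residuals after adduct
#: assignment are <= ~3 Da for these ~7-37 kDa proteins.
DEFAULT_MASS_TOL = 5.0

#: Reference retention times (min) on the validated two-stage gradient,
#: averaged over two systems x triplicate injections. Elution order
#: VP4 < VP1 < VP2 < VP0 < VP3.
REF_RT = {
    "VP4": 4.354,
    "VP1": 5.682,
    "VP2": 7.122,
    "VP0": 7.579,
    "VP3": 8.846,
}

#: Retention-time matching window (min) for peak -> VP assignment.
DEFAULT_RT_TOL = 0.3

#: Synthetic per-VP tryptophan counts (fluorescence response proxy).
#: Constraints honored: trp(VP4) = 0 (no Trp residue, negligible FLR
#: response) and trp(VP0) = trp(VP2) + trp(VP4) (cleavage conserves
#: residues). Absolute values are simulator fixtures.
SYNTHETIC_TRP = {
    "VP0": 5.0,
    "VP1": 6.0,
    "VP2": 5.0,
    "VP3": 4.0,
    "VP4": 0.0,
}

#: Gaussian peak sigma (min) for synthetic chromatograms; ~0.094 min FWHM,
#: consistent with baseline-resolved sub-2-micron UPLC peaks.
DEFAULT_PEAK_SIGMA = 0.04

#: Standard-curve range actually validated: particles per injection.
STANDARD_RANGE = (2.78e9, 1.04e11)

#: VP0/VP2 process-monitoring flag thresholds (ratio, not percent).
PROCESS_THRESHOLDS = {"intermediate": 0.04, "drug_substance": 0.01}

#: ESI acquisition window (m/z) of the Q-TOF method.
MZ_WINDOW = (400.0, 3000.0)


def default_vps(
    trp: dict[str, float] | None = None,
    peak_sigma: float = DEFAULT_PEAK_SIGMA,
    ref_rt: dict[str, float] | None = None,
) -> dict[str, VPDefinition]:
    """Build the five VP definitions from the reference constants.

    ``trp`` / ``ref_rt`` override the synthetic Trp fixture and the
    reference retention times per VP.
    """
    trp = {**SYNTHETIC_TRP, **(trp or {})}
    rts = {**REF_RT, **(ref_rt or {})}
    return {
        name: VPDefinition(
            name=name,
            calc_mass=CALC_MASS[name],
            trp_count=trp[name],
            ref_rt=rts[name],
            peak_sigma=peak_sigma,
        )
        for name in ("VP0", "VP1", "VP2", "VP3", "VP4")
    }


def default_species() -> list[ProteinSpecies]:
    """Candidate species list for intact-mass assignment."""
    return [ProteinSpecies(name, mass) for name, mass in CALC_MASS.items()]
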