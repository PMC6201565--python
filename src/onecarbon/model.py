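"""Reaction kinetics of hepatic one-carbon metabolism.

The model couples the folate cycle, the methionine cycle and the
PEMT-driven choline/betaine synthesis pathway in liver cytosol.  Every
reaction velocity is a pure function of metabolite concentrations and a
:class:`KineticParameters` set; long-range allosteric interactions (the
regulatory "red arrows": 5mTHF on GNMT, SAM+SAH on BHMT and CBS, betaine
on BHMT and CBS, SAM on MAT-I/III and MTHFR) enter as multiplicative
factors that can be ablated one-by-one through
:class:`RegulationSwitches`.

Units are fixed globally: concentrations in µM, velocities in µM/h,
time in hours.

The seventeen state variables are the four methionine-cycle metabolites
(Met, SAM, SAH, Hcy), the six folate species (5mTHF, THF, DHF,
CH2-THF, CH=THF, 10f-THF), serine, glycine and sarcosine, and the four
choline-pathway metabolites (PC, choline, betaine aldehyde, betaine).
The six folate species form a conserved moiety whose sum equals the
total-folate parameter.

Calibration
-----------
Km, Ki and allosteric constants are fixed from enzyme-kinetic
literature values used throughout this hepatic-OCM model family.  Vmax
values are *derived*: each one is back-solved so that a documented male
reference steady state (concentrations in :data:`MALE_REFERENCE_STATE`,
net fluxes in :data:`MALE_REFERENCE_FLUX`) is an exact equilibrium of
the system.  Vmax is proportional to enzyme expression, which varies
substantially between individuals, so a velocity scale pinned to a
reference steady state is the natural parameterization; it is also what
makes sex scaling (multiplying the Vmax of differentially expressed
enzymes) well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "STATE_NAMES",
    "REACTION_NAMES",
    "MetaboliteState",
    "KineticParameters",
    "RegulationSwitches",
    "MALE_REFERENCE_STATE",
    "MALE_REFERENCE_FLUX",
    "male_parameters",
    "male_reference_state",
    "v_pemt",
    "v_sms",
    "v_phld",
    "v_chox",
    "v_bah",
    "v_bhmt",
    "v_cbs",
    "v_gnmt",
    "core_rates",
]

# ---------------------------------------------------------------------------
# state variables
# ---------------------------------------------------------------------------

#: Order of the 17 state variables (used for all vectorized interfaces).
STATE_NAMES = (
    "met", "sam", "sah", "hcy",
    "f5mthf", "thf", "dhf", "ch2thf", "chthf", "f10thf",
    "ser", "gly", "sarc",
    "pc", "chol", "betald", "bet",
)

FOLATE_SPECIES = ("f5mthf", "thf", "dhf", "ch2thf", "chthf", "f10thf")


def _require_nonnegative(**values: float) -> None:
    for name, v in values.items():
        if v < 0:
            raise ValueError(f"concentration {name!r} must be >= 0, got {v}")


@dataclass
class MetaboliteState:
    """Concentrations (µM) of the 17 variable metabolites."""

    met: float
    sam: float
    sah: float
    hcy: float
    f5mthf: float
    thf: float
    dhf: float
    ch2thf: float
    chthf: float
    f10thf: float
    ser: float
    gly: float
    sarc: float
    pc: float
    chol: float
    betald: float
    bet: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"concentration {f.name!r} must be finite and >= 0, got {v}"
                )

    def to_array(self):
        import numpy as np

        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "MetaboliteState":
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, arr)})

    def folate_total(self) -> float:
        """Sum of the six folate species (the conserved moiety), µM."""
        return sum(getattr(self, n) for n in FOLATE_SPECIES)

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in STATE_NAMES}


# ---------------------------------------------------------------------------
# regulation switches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegulationSwitches:
    """On/off flags for the long-range allosteric interactions.

    All flags default to ``True`` (wild-type model).  Turning a flag off
    replaces exactly one multiplicative regulation factor by 1.
    """

    gnmt_inhibition_by_5mthf: bool = True
    cbs_activation_by_sam_sah: bool = True
    cbs_activation_by_betaine: bool = True
    bhmt_inhibition_by_sam_sah: bool = True
    bhmt_activation_by_betaine: bool = True
    mat1_inhibition_by_sam: bool = True
    mat3_activation_by_sam: bool = True
    mthfr_inhibition_by_sam: bool = True

    def with_flag(self, flag: str, on: bool) -> "RegulationSwitches":
        if flag not in {f.name for f in fields(self)}:
            raise KeyError(f"unknown regulation flag {flag!r}")
        return replace(self, **{flag: on})


# ---------------------------------------------------------------------------
# kinetic parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticParameters:
    """Every kinetic constant of the model.

    Vmax in µM/h, Km/Ki and clamped concentrations in µM, first-order
    use/export constants in 1/h, boundary inputs in µM/h.  Constructed
    via :func:`male_parameters` (the calibrated baseline) and modified
    with :mod:`onecarbon.scenarios`.
    """

    # --- choline / betaine synthesis pathway (printed rate laws) ---
    pemt_vmax: float
    pemt_km_sam: float
    pemt_ki_sah: float
    pemt_km_pe: float
    pemt_pe_prefactor: float
    sms_vmax: float
    sms_km: float
    phld_vmax: float
    phld_km: float
    chox_vmax: float
    chox_km: float
    bah_vmax: float
    bah_km: float

    # --- BHMT ---
    bhmt_vmax: float
    bhmt_km_hcy: float
    bhmt_km_bet: float
    bhmt_inh_coeff: float      # exponential coefficient on SAM+SAH
    bhmt_ref_samsah: float     # normal male SAM+SAH, µM
    bhmt_act_slope: float      # fractional activation per ref-betaine
    bhmt_ref_bet: float        # normal male betaine, µM

    # --- CBS ---
    cbs_vmax: float
    cbs_km_hcy: float
    cbs_act_amp: float         # SAM+SAH activation amplitude
    cbs_act_k: float           # SAM+SAH activation half-constant, µM
    cbs_ref_samsah: float
    cbs_bet_amp: float         # betaine activation amplitude
    cbs_bet_k: float           # betaine activation half-constant, µM
    cbs_ref_bet: float

    # --- methionine cycle core ---
    mat1_vmax: float
    mat1_km: float
    mat1_inh_base: float
    mat1_inh_amp: float
    mat1_inh_coeff: float
    mat1_ref_sam: float
    mat3_vmax: float
    mat3_km: float
    mat3_hill: float
    mat3_act_amp: float
    mat3_act_k: float
    mat3_ref_sam: float
    gnmt_vmax: float
    gnmt_km_sam: float
    gnmt_hill: float
    gnmt_km_gly: float
    gnmt_ki_sah: float
    gnmt_ki_5mthf: float       # dissociation constant of each 5mTHF site
    dnmt_vmax: float
    dnmt_km: float
    dnmt_ki_sah: float
    gamt_vmax: float
    gamt_km: float
    gamt_ki_sah: float
    as3mt_vmax: float
    as3mt_km: float
    as3mt_ki_sah: float
    sahh_vmax_f: float
    sahh_km_sah: float
    sahh_vmax_r: float
    sahh_km_hcy: float
    ms_vmax: float
    ms_km_5mthf: float
    ms_km_hcy: float

    # --- folate cycle core ---
    mthfr_vmax: float
    mthfr_km: float
    mthfr_ki_sam: float
    mthfr_ref_sam: float
    shmt_vmax_f: float
    shmt_km_ser: float
    shmt_km_thf: float
    shmt_vmax_r: float
    shmt_km_gly: float
    shmt_km_ch2: float
    ne_k1: float               # µM⁻¹ h⁻¹, THF + HCHO -> CH2-THF
    ne_k2: float               # h⁻¹, CH2-THF -> THF + HCHO
    ne_hcho: float             # clamped formaldehyde, µM
    ts_vmax: float
    ts_km: float
    dhfr_vmax: float
    dhfr_km: float
    aicart_vmax: float
    aicart_km: float
    pgt_vmax: float
    pgt_km: float
    mtd_vmax_f: float
    mtd_km_ch2: float
    mtd_vmax_r: float
    mtd_km_chf: float
    mtch_vmax_f: float
    mtch_km_chf: float
    mtch_vmax_r: float
    mtch_km_10f: float
    fts_vmax: float
    fts_km_thf: float
    ftd_vmax: float
    ftd_km: float

    # --- clamped concentrations (boundary species, µM) ---
    pe: float                  # phosphatidylethanolamine
    sphmy: float               # sphingomyelin

    # --- boundary fluxes and pool turnover ---
    met_input: float           # µM/h, dietary methionine into Met
    folate_total: float        # µM, conserved folate moiety
    bet_input: float           # µM/h, dietary betaine into Bet
    chol_use_k: float          # 1/h, choline consumption/export
    bet_use_vmax: float        # µM/h, saturable betaine consumption/export
    bet_use_km: float          # µM, half-constant of betaine consumption
    ser_input: float           # µM/h, serine supply
    ser_use_k: float           # 1/h, serine consumption/export
    gly_use_k: float           # 1/h, glycine consumption/export
    sarc_use_k: float          # 1/h, sarcosine removal

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name!r} must be finite, got {v}")
            if f.name.endswith(("_vmax", "_vmax_f", "_vmax_r")) or "_km" in f.name \
                    or "_ki" in f.name:
                if v <= 0:
                    raise ValueError(
                        f"parameter {f.name!r} must be > 0, got {v}"
                    )
            elif f.name in ("pe", "sphmy") and v < 0:
                raise ValueError(f"clamp {f.name!r} must be >= 0, got {v}")


# ---------------------------------------------------------------------------
# individual rate laws of the choline/betaine pathway
# ---------------------------------------------------------------------------


def v_pemt(sam: float, sah: float, pe: float, p: KineticParameters) -> float:
    """Phosphatidylethanolamine N-methyltransferase rate, µM/h.

    Michaelis-Menten in SAM with non-competitive SAH inhibition, times a
    saturating PE factor (prefactor 25).
    """
    _require_nonnegative(sam=sam, sah=sah, pe=pe)
    sam_term = p.pemt_vmax * sam / ((p.pemt_km_sam + sam) * (1.0 + sah / p.pemt_ki_sah))
    pe_term = p.pemt_pe_prefactor * pe / (p.pemt_km_pe + pe)
    return sam_term * pe_term


def v_sms(sphmy: float, p: KineticParameters) -> float:
    """Sphingomyelin-driven flux into the PC pool (sphingomyelinase
    direction of sphingomyelin synthase), µM/h."""
    _require_nonnegative(sphmy=sphmy)
    return p.sms_vmax * sphmy / (p.sms_km + sphmy)


def v_phld(pc: float, p: KineticParameters) -> float:
    """Phospholipase-D: PC -> choline, µM/h."""
    _require_nonnegative(pc=pc)
    return p.phld_vmax * pc / (p.phld_km + pc)


def v_chox(chol: float, p: KineticParameters) -> float:
    """Choline oxidase: choline -> betaine aldehyde, µM/h."""
    _require_nonnegative(chol=chol)
    return p.chox_vmax * chol / (p.chox_km + chol)


def v_bah(betald: float, p: KineticParameters) -> float:
    """Betaine aldehyde dehydrogenase: betaine aldehyde -> betaine, µM/h."""
    _require_nonnegative(betald=betald)
    return p.bah_vmax * betald / (p.bah_km + betald)


def bhmt_sam_sah_factor(sam: float, sah: float, p: KineticParameters) -> float:
    """Exponential inhibition of BHMT by SAM+SAH, normalized to 1 at the
    normal male steady state (SAM+SAH = 32.3 µM)."""
    c = p.bhmt_inh_coeff
    return math.exp(-c * (sam + sah)) / math.exp(-c * p.bhmt_ref_samsah)


def bhmt_betaine_factor(bet: float, p: KineticParameters) -> float:
    """Linear activation of BHMT by betaine (slope 16% per reference
    betaine); equals 1 at the normal male betaine of 315 µM."""
    return 1.0 + p.bhmt_act_slope * (bet - p.bhmt_ref_bet) / p.bhmt_ref_bet


def v_bhmt(hcy: float, bet: float, sam: float, sah: float,
           p: KineticParameters, sw: RegulationSwitches) -> float:
    """Betaine-homocysteine methyltransferase rate, µM/h.

    Product of a two-substrate MM term (Hcy, Bet), the SAM+SAH
    inhibition factor, and the betaine activation factor.  Both
    regulation factors equal exactly 1 at the normal male steady state.
    """
    _require_nonnegative(hcy=hcy, bet=bet, sam=sam, sah=sah)
    mm = (p.bhmt_vmax * hcy * bet
          / ((p.bhmt_km_hcy + hcy) * (p.bhmt_km_bet + bet)))
    f_inh = bhmt_sam_sah_factor(sam, sah, p) if sw.bhmt_inhibition_by_sam_sah else 1.0
    f_act = bhmt_betaine_factor(bet, p) if sw.bhmt_activation_by_betaine else 1.0
    return mm * f_inh * f_act


def cbs_sam_sah_factor(sam: float, sah: float, p: KineticParameters) -> float:
    """Sigmoidal activation of CBS by SAM+SAH, normalized to 1 at
    SAM+SAH = 32.3 µM."""
    s = sam + sah
    raw = p.cbs_act_amp * s * s / (p.cbs_act_k ** 2 + s * s)
    r = p.cbs_ref_samsah
    ref = p.cbs_act_amp * r * r / (p.cbs_act_k ** 2 + r * r)
    return raw / ref


def cbs_betaine_factor(bet: float, p: KineticParameters) -> float:
    """Saturating activation of CBS by betaine above its male reference.

    Equals 1 for bet <= 315 µM (Heaviside gate, H(0) = 0) and rises
    continuously toward 1.2 as betaine increases.
    """
    excess = bet - p.cbs_ref_bet
    if excess <= 0.0:
        return 1.0
    return 1.0 + p.cbs_bet_amp * excess / (p.cbs_bet_k + excess)


def v_cbs(hcy: float, sam: float, sah: float, bet: float,
          p: KineticParameters, sw: RegulationSwitches) -> float:
    """Cystathionine β-synthase rate (transsulfuration entry), µM/h."""
    _require_nonnegative(hcy=hcy, sam=sam, sah=sah, bet=bet)
    mm = p.cbs_vmax * hcy / (p.cbs_km_hcy + hcy)
    f_ss = cbs_sam_sah_factor(sam, sah, p) if sw.cbs_activation_by_sam_sah else 1.0
    f_bet = cbs_betaine_factor(bet, p) if sw.cbs_activation_by_betaine else 1.0
    return mm * f_ss * f_bet


# ---------------------------------------------------------------------------
# methionine-cycle and folate-cycle rate laws
# ---------------------------------------------------------------------------


def gnmt_5mthf_factor(f5mthf: float, p: KineticParameters) -> float:
    """Two-site 5mTHF inhibition of GNMT.

    GNMT carries two independent 5mTHF binding sites with dissociation
    constant ``gnmt_ki_5mthf``; one occupied site leaves 50% activity,
    two occupied sites abolish activity.  With site occupancy
    q = f/(Ki+f) the expected activity (1-q)² + 2·q(1-q)·½ collapses to
    Ki/(Ki+f): 1 at zero inhibitor, monotone decreasing, -> 0 as
    5mTHF -> ∞.
    """
    return p.gnmt_ki_5mthf / (p.gnmt_ki_5mthf + f5mthf)


def v_gnmt(sam: float, sah: float, f5mthf: float,
           p: KineticParameters, sw: RegulationSwitches,
           gly: float | None = None) -> float:
    """Glycine N-methyltransferase rate, µM/h.

    Hill kinetics in SAM (coefficient 2.3), MM in glycine, competitive
    SAH inhibition, times the two-site 5mTHF inhibition factor.  When
    ``gly`` is omitted the reference glycine concentration is used.
    """
    _require_nonnegative(sam=sam, sah=sah, f5mthf=f5mthf)
    if gly is None:
        gly = MALE_REFERENCE_STATE["gly"]
    _require_nonnegative(gly=gly)
    h = p.gnmt_hill
    sam_h = sam ** h
    hill = sam_h / (p.gnmt_km_sam ** h + sam_h)
    gly_f = gly / (p.gnmt_km_gly + gly)
    sah_f = 1.0 / (1.0 + sah / p.gnmt_ki_sah)
    inh = gnmt_5mthf_factor(f5mthf, p) if sw.gnmt_inhibition_by_5mthf else 1.0
    return p.gnmt_vmax * hill * gly_f * sah_f * inh


def _mat1_factor(sam: float, p: KineticParameters) -> float:
    raw = p.mat1_inh_base + p.mat1_inh_amp * math.exp(-p.mat1_inh_coeff * sam)
    ref = p.mat1_inh_base + p.mat1_inh_amp * math.exp(-p.mat1_inh_coeff * p.mat1_ref_sam)
    return raw / ref


def _mat3_factor(sam: float, p: KineticParameters) -> float:
    raw = 1.0 + p.mat3_act_amp * (sam / (sam + p.mat3_act_k)) ** 2
    ref = 1.0 + p.mat3_act_amp * (p.mat3_ref_sam / (p.mat3_ref_sam + p.mat3_act_k)) ** 2
    return raw / ref


def _mthfr_factor(sam: float, p: KineticParameters) -> float:
    return (p.mthfr_ki_sam + p.mthfr_ref_sam) / (p.mthfr_ki_sam + sam)


def core_rates(state: MetaboliteState, p: KineticParameters,
               sw: RegulationSwitches) -> dict[str, float]:
    """All reaction velocities (µM/h) at a given state.

    Irreversible reactions are nonnegative; the reversible steps SAHH,
    SHMT, NE, MTD and MTCH are net-signed with the positive direction
    being SAH->Hcy, Ser+THF->Gly+CH2-THF, THF->CH2-THF, CH2-THF->CH=THF
    and CH=THF->10f-THF respectively.  ``met_input``, ``bet_input``,
    ``ser_input`` and the first-order use terms are included so that the
    mapping carries every arrow of the network.
    """
    s = state
    rates: dict[str, float] = {}

    # methionine cycle
    mat1_mm = p.mat1_vmax * s.met / (p.mat1_km + s.met)
    rates["MAT1"] = mat1_mm * (_mat1_factor(s.sam, p) if sw.mat1_inhibition_by_sam else 1.0)
    met_h = s.met ** p.mat3_hill
    mat3_mm = p.mat3_vmax * met_h / (p.mat3_km + met_h)
    rates["MAT3"] = mat3_mm * (_mat3_factor(s.sam, p) if sw.mat3_activation_by_sam else 1.0)
    rates["GNMT"] = v_gnmt(s.sam, s.sah, s.f5mthf, p, sw, gly=s.gly)
    rates["DNMT"] = p.dnmt_vmax * s.sam / (s.sam + p.dnmt_km * (1.0 + s.sah / p.dnmt_ki_sah))
    rates["GAMT"] = p.gamt_vmax * s.sam / (s.sam + p.gamt_km * (1.0 + s.sah / p.gamt_ki_sah))
    rates["AS3MT"] = p.as3mt_vmax * s.sam / (s.sam + p.as3mt_km * (1.0 + s.sah / p.as3mt_ki_sah))
    rates["PEMT"] = v_pemt(s.sam, s.sah, p.pe, p)
    rates["SAHH"] = (p.sahh_vmax_f * s.sah / (p.sahh_km_sah + s.sah)
                     - p.sahh_vmax_r * s.hcy / (p.sahh_km_hcy + s.hcy))
    rates["MS"] = (p.ms_vmax * (s.f5mthf / (p.ms_km_5mthf + s.f5mthf))
                   * (s.hcy / (p.ms_km_hcy + s.hcy)))
    rates["BHMT"] = v_bhmt(s.hcy, s.bet, s.sam, s.sah, p, sw)
    rates["CBS"] = v_cbs(s.hcy, s.sam, s.sah, s.bet, p, sw)

    # folate cycle
    mthfr_mm = p.mthfr_vmax * s.ch2thf / (p.mthfr_km + s.ch2thf)
    rates["MTHFR"] = mthfr_mm * (_mthfr_factor(s.sam, p) if sw.mthfr_inhibition_by_sam else 1.0)
    rates["SHMT"] = (p.shmt_vmax_f * (s.ser / (p.shmt_km_ser + s.ser))
                     * (s.thf / (p.shmt_km_thf + s.thf))
                     - p.shmt_vmax_r * (s.gly / (p.shmt_km_gly + s.gly))
                     * (s.ch2thf / (p.shmt_km_ch2 + s.ch2thf)))
    rates["NE"] = p.ne_k1 * s.thf * p.ne_hcho - p.ne_k2 * s.ch2thf
    rates["TS"] = p.ts_vmax * s.ch2thf / (p.ts_km + s.ch2thf)
    rates["DHFR"] = p.dhfr_vmax * s.dhf / (p.dhfr_km + s.dhf)
    rates["AICART"] = p.aicart_vmax * s.f10thf / (p.aicart_km + s.f10thf)
    rates["PGT"] = p.pgt_vmax * s.f10thf / (p.pgt_km + s.f10thf)
    rates["MTD"] = (p.mtd_vmax_f * s.ch2thf / (p.mtd_km_ch2 + s.ch2thf)
                    - p.mtd_vmax_r * s.chthf / (p.mtd_km_chf + s.chthf))
    rates["MTCH"] = (p.mtch_vmax_f * s.chthf / (p.mtch_km_chf + s.chthf)
                     - p.mtch_vmax_r * s.f10thf / (p.mtch_km_10f + s.f10thf))
    rates["FTS"] = p.fts_vmax * s.thf / (p.fts_km_thf + s.thf)
    rates["FTD"] = p.ftd_vmax * s.f10thf / (p.ftd_km + s.f10thf)

    # choline / betaine synthesis pathway
    rates["SMS"] = v_sms(p.sphmy, p)
    rates["PHLD"] = v_phld(s.pc, p)
    rates["CHOX"] = v_chox(s.chol, p)
    rates["BAH"] = v_bah(s.betald, p)

    # boundary fluxes
    rates["MET_IN"] = p.met_input
    rates["BET_IN"] = p.bet_input
    rates["SER_IN"] = p.ser_input
    rates["CHOL_USE"] = p.chol_use_k * s.chol
    rates["BET_USE"] = p.bet_use_vmax * s.bet / (p.bet_use_km + s.bet)
    rates["SER_USE"] = p.ser_use_k * s.ser
    rates["GLY_USE"] = p.gly_use_k * s.gly
    rates["SARC_USE"] = p.sarc_use_k * s.sarc

    for name, v in rates.items():
        if not math.isfinite(v):
            raise ArithmeticError(f"rate {name} is not finite: {v}")
    return rates


#: Reaction names produced by :func:`core_rates`, in a stable order.
REACTION_NAMES = (
    "MAT1", "MAT3", "GNMT", "DNMT", "GAMT", "AS3MT", "PEMT",
    "SAHH", "MS", "BHMT", "CBS",
    "MTHFR", "SHMT", "NE", "TS", "DHFR", "AICART", "PGT",
    "MTD", "MTCH", "FTS", "FTD",
    "SMS", "PHLD", "CHOX", "BAH",
    "MET_IN", "BET_IN", "SER_IN",
    "CHOL_USE", "BET_USE", "SER_USE", "GLY_USE", "SARC_USE",
)

METHYLTRANSFERASES = ("GNMT", "DNMT", "GAMT", "AS3MT", "PEMT")


# ---------------------------------------------------------------------------
# male reference steady state and Vmax calibration
# ---------------------------------------------------------------------------

#: Male reference concentrations, µM.  Printed normal-male values where
#: the tables give them (SAM 29.03, SAM+SAH 32.3 => SAH 3.27, Hcy 1.80,
#: choline 60, betaine 315); the remaining pools are hepatic literature
#: values used throughout this model family.  PC and betaine aldehyde
#: are back-solved from pathway flux balance below.
MALE_REFERENCE_STATE: dict[str, float] = {
    "met": 53.5,
    "sam": 29.03,
    "sah": 3.27,
    "hcy": 1.80,
    "f5mthf": 5.16,
    "thf": 6.73,
    "dhf": 0.027,
    "ch2thf": 0.94,
    "chthf": 1.15,
    "f10thf": 5.993,
    "ser": 468.0,
    "gly": 924.0,
    "sarc": 10.0,
    "pc": float("nan"),      # filled by _calibrate()
    "chol": 60.0,
    "betald": float("nan"),  # filled by _calibrate()
    "bet": 315.0,
}

#: Primary flux choices (µM/h) from which the full consistent reference
#: flux vector is derived.  vBHMT = 35.48 is the printed male BHMT
#: velocity; the methionine input and the partition of the
#: transmethylation flux over the five methyltransferases, and of the
#: folate-cycle flux over its branches, are calibration choices.
_FLUX_PRIMARIES: dict[str, float] = {
    "met_input": 60.0,
    "ms": 40.5,          # = MTHFR flux (5mTHF node balance)
    "bhmt": 35.48,       # printed
    "pemt": 26.0,
    "gnmt": 34.3,
    "dnmt": 15.0,
    "as3mt": 2.48,
    "mat3": 25.48,
    "sahh_ratio": 1.25,  # forward SAHH exchange / transmethylation flux
    "ts": 5.0,
    "mtd": 55.0,         # net CH2-THF -> CH=THF
    "mtd_r": 25.0,       # reverse exchange
    "mtch_r": 15.0,
    "aicart": 10.0,
    "pgt": 10.0,
    "fts": 20.0,
    "ne": 20.0,          # net nonenzymatic THF -> CH2-THF
    "shmt_r": 5.0,       # reverse SHMT exchange
    "ser_in": 300.0,
}


def _reference_fluxes(prim: dict[str, float]) -> dict[str, float]:
    """Expand the primary flux choices into a stoichiometrically
    consistent male reference flux vector."""
    transmeth = prim["met_input"] + prim["ms"] + prim["bhmt"]
    gamt = transmeth - prim["pemt"] - prim["gnmt"] - prim["dnmt"] - prim["as3mt"]
    if gamt <= 0:
        raise ValueError("methyltransferase split exceeds transmethylation flux")
    shmt_net = prim["ms"] + prim["ts"] + prim["mtd"] - prim["ne"]
    return {
        "MET_IN": prim["met_input"],
        "MS": prim["ms"],
        "BHMT": prim["bhmt"],
        "CBS": prim["met_input"],
        "PEMT": prim["pemt"],
        "GNMT": prim["gnmt"],
        "DNMT": prim["dnmt"],
        "GAMT": gamt,
        "AS3MT": prim["as3mt"],
        "MAT1": transmeth - prim["mat3"],
        "MAT3": prim["mat3"],
        "SAHH_F": prim["sahh_ratio"] * transmeth,
        "SER_IN": prim["ser_in"],
        "MTHFR": prim["ms"],
        "SHMT_F": shmt_net + prim["shmt_r"],
        "SHMT_R": prim["shmt_r"],
        "NE": prim["ne"],
        "TS": prim["ts"],
        "DHFR": prim["ts"],
        "MTD_F": prim["mtd"] + prim["mtd_r"],
        "MTD_R": prim["mtd_r"],
        "MTCH_F": prim["mtd"] + prim["mtch_r"],
        "MTCH_R": prim["mtch_r"],
        "FTS": prim["fts"],
        "FTD": prim["mtd"] + prim["fts"] - prim["aicart"] - prim["pgt"],
        "AICART": prim["aicart"],
        "PGT": prim["pgt"],
    }


MALE_REFERENCE_FLUX: dict[str, float] = _reference_fluxes(_FLUX_PRIMARIES)

# Structural constants (Km/Ki/allosteric), fixed independently of the
# calibration.  Printed Methods constants are used verbatim for the
# choline pathway, BHMT and CBS; the rest are the model family's
# literature values.
_STRUCTURAL = dict(
    pemt_vmax=98.0, pemt_km_sam=18.2, pemt_ki_sah=3.8, pemt_km_pe=5000.0,
    pemt_pe_prefactor=25.0,
    sms_vmax=30.0, sms_km=20.0,
    phld_vmax=525.0, phld_km=400.0,
    chox_vmax=125.0, chox_km=200.0,
    bah_vmax=45.0, bah_km=250.0,
    bhmt_km_hcy=12.0, bhmt_km_bet=2000.0,
    bhmt_inh_coeff=0.0021, bhmt_ref_samsah=32.3,
    bhmt_act_slope=0.16, bhmt_ref_bet=315.0,
    cbs_km_hcy=1000.0,
    cbs_act_amp=1.2, cbs_act_k=30.0, cbs_ref_samsah=32.3,
    cbs_bet_amp=0.2, cbs_bet_k=10.0, cbs_ref_bet=315.0,
    mat1_km=41.0, mat1_inh_base=0.23, mat1_inh_amp=0.8, mat1_inh_coeff=0.0026,
    mat1_ref_sam=29.03,
    mat3_km=20000.0, mat3_hill=1.21, mat3_act_amp=5.7, mat3_act_k=600.0,
    mat3_ref_sam=29.03,
    gnmt_km_sam=4500.0, gnmt_hill=1.66, gnmt_km_gly=130.0, gnmt_ki_sah=18.0,
    gnmt_ki_5mthf=0.8,
    dnmt_km=1.4, dnmt_ki_sah=1.4,
    gamt_km=20.0, gamt_ki_sah=16.0,
    as3mt_km=3.0, as3mt_ki_sah=3.0,
    sahh_km_sah=1.5, sahh_km_hcy=150.0,
    ms_km_5mthf=25.0, ms_km_hcy=0.1,
    mthfr_km=50.0, mthfr_ki_sam=2.2, mthfr_ref_sam=29.03,
    shmt_km_ser=600.0, shmt_km_thf=50.0, shmt_km_gly=10000.0, shmt_km_ch2=3200.0,
    ne_k1=0.03, ne_hcho=500.0,
    ts_km=6.3, dhfr_km=0.5, aicart_km=5.9, pgt_km=4.9,
    mtd_km_ch2=2.0, mtd_km_chf=10.0, mtch_km_chf=250.0, mtch_km_10f=100.0,
    fts_km_thf=3.0, ftd_km=20.0,
    sphmy=110.0,
    bet_use_km=4000.0,
)


def _calibrate() -> dict[str, float]:
    """Back-solve every Vmax (and the derived boundary parameters) so the
    male reference state is an exact equilibrium."""
    c = dict(_STRUCTURAL)
    R = MALE_REFERENCE_STATE
    F = MALE_REFERENCE_FLUX
    sam, sah, hcy, met = R["sam"], R["sah"], R["hcy"], R["met"]
    f5, thf, ch2, chf, f10, dhf = (R["f5mthf"], R["thf"], R["ch2thf"],
                                   R["chthf"], R["f10thf"], R["dhf"])

    # -- choline pathway boundary parameters --
    # PE clamp: the printed PEMT law must carry the reference PEMT flux.
    pemt_sam = (c["pemt_vmax"] * sam
                / ((c["pemt_km_sam"] + sam) * (1.0 + sah / c["pemt_ki_sah"])))
    pe_sat = F["PEMT"] / pemt_sam / c["pemt_pe_prefactor"]
    c["pe"] = c["pemt_km_pe"] * pe_sat / (1.0 - pe_sat)

    # Betaine boundary: input and first-order use are pinned jointly by
    # the printed male (chol 60, bet 315, vBHMT 35.48) and female
    # (chol 100, bet 632, vBHMT 40.96) steady states.
    v_chox_m = c["chox_vmax"] * 60.0 / (c["chox_km"] + 60.0)
    v_chox_f = c["chox_vmax"] * 100.0 / (c["chox_km"] + 100.0)
    kb = c["bet_use_km"]
    c["bet_use_vmax"] = ((v_chox_f - v_chox_m) - (40.96 - 35.48)) \
        / (632.0 / (kb + 632.0) - 315.0 / (kb + 315.0))
    c["bet_input"] = 35.48 - v_chox_m + c["bet_use_vmax"] * 315.0 / (kb + 315.0)

    # Sphingomyelin clamp (a structural choice): the male SMS flux
    # closes the PC balance against the PhL-D flux required by the
    # choline node, with a female-consistent first-order choline use.
    v_sms_ref = c["sms_vmax"] * c["sphmy"] / (c["sms_km"] + c["sphmy"])
    v_phld_ref = F["PEMT"] + v_sms_ref
    c["chol_use_k"] = (v_phld_ref - v_chox_m) / 60.0
    # PC and betaine aldehyde back-solved from their node balances.
    R["pc"] = c["phld_km"] * v_phld_ref / (c["phld_vmax"] - v_phld_ref)
    R["betald"] = c["bah_km"] * v_chox_m / (c["bah_vmax"] - v_chox_m)

    # -- methionine cycle Vmax --
    c["mat1_vmax"] = F["MAT1"] / (met / (c["mat1_km"] + met))
    met_h = met ** c["mat3_hill"]
    c["mat3_vmax"] = F["MAT3"] / (met_h / (c["mat3_km"] + met_h))
    sam_h = sam ** c["gnmt_hill"]
    gnmt_sat = (sam_h / (c["gnmt_km_sam"] ** c["gnmt_hill"] + sam_h)
                * (R["gly"] / (c["gnmt_km_gly"] + R["gly"]))
                * (1.0 / (1.0 + sah / c["gnmt_ki_sah"]))
                * (c["gnmt_ki_5mthf"] / (c["gnmt_ki_5mthf"] + f5)))
    c["gnmt_vmax"] = F["GNMT"] / gnmt_sat
    c["dnmt_vmax"] = F["DNMT"] / (sam / (sam + c["dnmt_km"] * (1 + sah / c["dnmt_ki_sah"])))
    c["gamt_vmax"] = F["GAMT"] / (sam / (sam + c["gamt_km"] * (1 + sah / c["gamt_ki_sah"])))
    c["as3mt_vmax"] = F["AS3MT"] / (sam / (sam + c["as3mt_km"] * (1 + sah / c["as3mt_ki_sah"])))
    transmeth = F["GNMT"] + F["DNMT"] + F["GAMT"] + F["AS3MT"] + F["PEMT"]
    c["sahh_vmax_f"] = F["SAHH_F"] / (sah / (c["sahh_km_sah"] + sah))
    c["sahh_vmax_r"] = (F["SAHH_F"] - transmeth) / (hcy / (c["sahh_km_hcy"] + hcy))
    c["ms_vmax"] = F["MS"] / ((f5 / (c["ms_km_5mthf"] + f5)) * (hcy / (c["ms_km_hcy"] + hcy)))
    c["bhmt_vmax"] = F["BHMT"] / ((hcy / (c["bhmt_km_hcy"] + hcy))
                                  * (315.0 / (c["bhmt_km_bet"] + 315.0)))
    c["cbs_vmax"] = F["CBS"] / (hcy / (c["cbs_km_hcy"] + hcy))

    # -- folate cycle Vmax --
    c["mthfr_vmax"] = F["MTHFR"] / (ch2 / (c["mthfr_km"] + ch2))
    c["shmt_vmax_f"] = F["SHMT_F"] / ((R["ser"] / (c["shmt_km_ser"] + R["ser"]))
                                      * (thf / (c["shmt_km_thf"] + thf)))
    c["shmt_vmax_r"] = F["SHMT_R"] / ((R["gly"] / (c["shmt_km_gly"] + R["gly"]))
                                      * (ch2 / (c["shmt_km_ch2"] + ch2)))
    c["ne_k2"] = (c["ne_k1"] * thf * c["ne_hcho"] - F["NE"]) / ch2
    c["ts_vmax"] = F["TS"] / (ch2 / (c["ts_km"] + ch2))
    c["dhfr_vmax"] = F["DHFR"] / (dhf / (c["dhfr_km"] + dhf))
    c["aicart_vmax"] = F["AICART"] / (f10 / (c["aicart_km"] + f10))
    c["pgt_vmax"] = F["PGT"] / (f10 / (c["pgt_km"] + f10))
    c["mtd_vmax_f"] = F["MTD_F"] / (ch2 / (c["mtd_km_ch2"] + ch2))
    c["mtd_vmax_r"] = F["MTD_R"] / (chf / (c["mtd_km_chf"] + chf))
    c["mtch_vmax_f"] = F["MTCH_F"] / (chf / (c["mtch_km_chf"] + chf))
    c["mtch_vmax_r"] = F["MTCH_R"] / (f10 / (c["mtch_km_10f"] + f10))
    c["fts_vmax"] = F["FTS"] / (thf / (c["fts_km_thf"] + thf))
    c["ftd_vmax"] = F["FTD"] / (f10 / (c["ftd_km"] + f10))

    # -- amino-acid pools --
    c["ser_input"] = F["SER_IN"]
    c["ser_use_k"] = (F["SER_IN"] - (F["SHMT_F"] - F["SHMT_R"])) / R["ser"]
    c["gly_use_k"] = (F["SHMT_F"] - F["SHMT_R"] - F["GNMT"]) / R["gly"]
    c["sarc_use_k"] = F["GNMT"] / R["sarc"]

    # -- boundary --
    c["met_input"] = F["MET_IN"]
    c["folate_total"] = f5 + thf + dhf + ch2 + chf + f10
    return c


_MALE: dict[str, float] = _calibrate()


def male_parameters() -> KineticParameters:
    """The calibrated male baseline parameter set."""
    return KineticParameters(**_MALE)


def male_reference_state() -> MetaboliteState:
    """The male reference steady state used for calibration."""
    return MetaboliteState(**MALE_REFERENCE_STATE)
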