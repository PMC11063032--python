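"""Published reference values for sunflower (Helianthus annuus L. var. S1-278).

A laboratory germination study of this cultivar scored 10-seed dishes daily
under a 4 temperature (15, 20, 25, 30 degC) x 5 water potential (0 to -1.2
MPa, PEG 6000) grid with 3 replicates, and reported per-treatment
thermal/hydro/hydrothermal constants plus population-level fits.  Those
printed values are bundled here as inputs for consistency checks and as the
default "true" parameters of the synthetic study generator.

``SUNFLOWER_GRID`` holds the per-treatment constants as printed, keyed by
(temperature degC, psi MPa) with columns (TTsub degC.h, TTsupra degC.h,
thetaH MPa.h, thetaHTT MPa.degC.h, GR_tt 1/h, GR_ht 1/h).  The printed
columns are mutually consistent under the constants Tb = 10 degC, Tc = 45
degC, psib = -1.5 MPa (``GRID_IMPLIED``), i.e. all columns derive from the
TTsub column via tg = TTsub/(T - Tb): TTsupra = (Tc - T) tg, thetaHTT =
(psi - psib)(T - Tb) tg, thetaH = (0 - psib) tg (the hydrotime referenced
to distilled water in every cell) and GR_ht = GR_tt (psi - psib)/(0 - psib)
— except a handful of corrupted cells at 15 degC listed in
``GRID_INCONSISTENT_CELLS``.

``SUNFLOWER_POPULATION`` holds the reported population parameters
(psi_b(50) = -0.87 MPa, sigma_psib = 0.20 MPa, hydrotime constant at the
optimum 56.43 MPa.h, kT = 0.104 MPa/degC) and ``SUNFLOWER_CARDINAL`` the
reported cardinal temperatures (Tb = 6.8, To = 20, Tc = 30 degC).  The
single hydrotime constant is interpreted as theta_HTT/(To - Tb), giving
theta_HTT = 744.876 MPa.degC.h.
"""
from __future__ import annotations

from .models import HTTParams

# (T degC, psi MPa) -> (TTsub, TTsupra, thetaH, thetaHTT, GR_tt, GR_ht)
SUNFLOWER_GRID: dict[tuple[float, float], tuple[float, ...]] = {
    (15, 0.0):  (187.2, 1123.2, 56.16, 280.8, 0.027562, 0.027562),
    (15, -0.3): (129.6, 777.6, 38.58, 155.52, 0.039195, 0.031608),
    (15, -0.6): (97.65, 585.6, 28.68, 87.84, 0.052403, 0.03213),
    (15, -0.9): (79.2, 475.2, 22.86, 47.52, 0.066032, 0.027562),
    (15, -1.2): (89.6, 537.6, 25.68, 26.88, 0.058544, 0.012311),
    (20, 0.0):  (272.0, 680.0, 40.8, 408.0, 0.03736, 0.03736),
    (20, -0.3): (219.2, 548.0, 32.88, 263.04, 0.046151, 0.036921),
    (20, -0.6): (192.0, 480.0, 28.8, 172.8, 0.054653, 0.032792),
    (20, -0.9): (179.2, 448.0, 26.88, 107.52, 0.060524, 0.02421),
    (20, -1.2): (137.6, 344.0, 20.64, 41.28, 0.073142, 0.014628),
    (25, 0.0):  (631.2, 841.6, 63.12, 946.8, 0.023844, 0.023844),
    (25, -0.3): (652.8, 870.4, 65.28, 783.36, 0.023188, 0.01855),
    (25, -0.6): (520.8, 694.4, 52.08, 468.72, 0.02959, 0.017754),
    (25, -0.9): (391.2, 521.6, 39.12, 234.72, 0.038659, 0.015464),
    (25, -1.2): (381.6, 508.8, 38.16, 114.48, 0.039308, 0.007862),
    (30, 0.0):  (995.2, 746.4, 74.64, 1492.8, 0.020141, 0.020141),
    (30, -0.3): (988.8, 741.6, 74.16, 1186.56, 0.020331, 0.016265),
    (30, -0.6): (726.4, 544.8, 54.48, 653.76, 0.027898, 0.016739),
    (30, -0.9): (460.8, 345.6, 34.56, 276.48, 0.043489, 0.017395),
    (30, -1.2): (422.4, 316.8, 31.68, 126.72, 0.047947, 0.009589),
}

GRID_COLUMNS = ("TTsub", "TTsupra", "thetaH", "thetaHTT", "GR_tt", "GR_ht")

#: constants under which the printed grid columns are mutually consistent
GRID_IMPLIED = {"Tb": 10.0, "Tc": 45.0, "psib": -1.5}

#: printed cells that do not satisfy the grid's own arithmetic (the 15 degC
#: -0.6 MPa TTsub entry 97.65 is evidently a misprint of 97.6, and the
#: 15 degC thetaH / GR_ht entries at stressed psi are internally corrupted)
GRID_INCONSISTENT_CELLS = {
    "TTsupra": {(15, -0.6)},
    "thetaHTT": {(15, -0.6)},
    "thetaH": {(15, -0.3), (15, -0.6), (15, -0.9), (15, -1.2)},
    "GR_ht": {(15, -0.3), (15, -0.6), (15, -0.9), (15, -1.2)},
}

#: reported population-level hydrothermal parameters
SUNFLOWER_POPULATION = {
    "psib50_MPa": -0.87,
    "sigma_psib_MPa": 0.20,
    "thetaH_at_To_MPah": 56.43,
    "kT_MPa_per_C": 0.104,
    "r_squared": 0.851,
}

#: reported cardinal temperatures, degC
SUNFLOWER_CARDINAL = {"Tb": 6.8, "To": 20.0, "Tc": 30.0}

#: study design grid
SUNFLOWER_TEMPERATURES = (15.0, 20.0, 25.0, 30.0)
SUNFLOWER_WATER_POTENTIALS = (0.0, -0.3, -0.6, -0.9, -1.2)


def sunflower_htt_params() -> HTTParams:
    """Reported population parameters as an :class:`HTTParams` object."""
    Tb = SUNFLOWER_CARDINAL["Tb"]
    To = SUNFLOWER_CARDINAL["To"]
    return HTTParams(
        thetaHTT=SUNFLOWER_POPULATION["thetaH_at_To_MPah"] * (To - Tb),
        Tb=Tb,
        psib50=SUNFLOWER_POPULATION["psib50_MPa"],
        sigma_psib=SUNFLOWER_POPULATION["sigma_psib_MPa"],
        kT=SUNFLOWER_POPULATION["kT_MPa_per_C"],
        To=To,
    )
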