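"""Study-scale replication experiments on synthetic ground truth.

Each function here reruns one quantitative analysis of the package at the
scale of the original study and reports summary estimates next to the known
ground truth: FRAP parameter recovery at the published acquisition geometry,
the solution-versus-nucleus diffusion contrast, FCS particle-number and
concentration recovery from 30-second traces, segmentation accuracy on
fields of touching nuclei, and the three-dose knockdown experiment.

These runners back both the acceptance test suite and the reproduction
script; all randomness is derived from a single seed argument.
"""

from __future__ import annotations

import math

import numpy as np

from .budget import AVOGADRO
from .config import RunConfig
from .fcs import (FcsFit, autocorrelate, calibrate_volume,
                  concentration_from_fit, fit_acf)
from .frap import analyze_trace
from .segmentation import otsu_three_class, segment_nuclei
from .simulate import (FcsGroundTruth, FrapGroundTruth, NucleusSpec,
                       SceneSpec, generate_fcs_trace, generate_frap_trace,
                       generate_scene, random_nuclei)

_MOD = 2_147_483_647


def _subseed(seed: int, stream: int, i: int = 0) -> int:
    """Derived seed for one replicate, kept below 2**31."""
    return (seed * stream + i) % _MOD


#: Nuclear FRAP ground truth: D = 0.7 um^2/s in a 2 um-radius bleach spot
#: with a 29% immobile fraction, on the published frame grid.
FRAP_NUCLEAR_TRUTH = dict(D=0.7, radius=2.0, mobile_fraction=0.71)
#: Solution FRAP: free diffusion at 107 um^2/s, 5 um-radius spot.
FRAP_SOLUTION_TRUTH = dict(D=107.0, radius=5.0, mobile_fraction=1.0)


def _tau_from_D(D: float, radius: float) -> float:
    """Invert D = 0.88 r^2 / (4 t_half), t_half = tau ln 2."""
    t_half = 0.88 * radius ** 2 / (4.0 * D)
    return t_half / math.log(2.0)


def frap_recovery_study(n_replicates: int = 200, seed: int = 0,
                        snr: float = 10.0) -> dict:
    """Median recovered D and immobile fraction over noisy nuclear traces.

    Geometry per the study: 10 prebleach + 70 recovery frames at 97 ms,
    2 um bleach radius; truth D = 0.7 um^2/s, mobile fraction 0.71.
    """
    truth = FRAP_NUCLEAR_TRUTH
    tau = _tau_from_D(truth["D"], truth["radius"])
    Ds, immobiles = [], []
    for i in range(n_replicates):
        gt = FrapGroundTruth(mobile_fraction=truth["mobile_fraction"], tau=tau,
                             bleach_radius=truth["radius"],
                             noise_sd=100.0 / snr, seed=_subseed(seed, 100003, i))
        fit = analyze_trace(generate_frap_trace(gt))
        Ds.append(fit.D)
        immobiles.append(fit.immobile_fraction)
    return {"median_D": float(np.median(Ds)),
            "median_immobile_fraction": float(np.median(immobiles)),
            "true_D": truth["D"], "true_immobile_fraction": 0.29,
            "n": n_replicates}


def frap_solution_contrast(n_replicates: int = 50, seed: int = 0) -> dict:
    """Recovered diffusion coefficients in solution vs nucleus.

    Solution traces use the wider 5 um bleach spot (recovery is nearly
    complete within two frames, so the contrast rests on the first post-
    bleach points); the recovered ratio should span two orders of magnitude.
    """
    out = {}
    for label, truth, snr in (("solution", FRAP_SOLUTION_TRUTH, 20.0),
                              ("nucleus", FRAP_NUCLEAR_TRUTH, 10.0)):
        tau = _tau_from_D(truth["D"], truth["radius"])
        Ds = []
        for i in range(n_replicates):
            gt = FrapGroundTruth(mobile_fraction=truth["mobile_fraction"],
                                 tau=tau, bleach_radius=truth["radius"],
                                 noise_sd=100.0 / snr, seed=_subseed(seed, 200003, i))
            Ds.append(analyze_trace(generate_frap_trace(gt)).D)
        out[f"median_D_{label}"] = float(np.median(Ds))
    out["ratio"] = out["median_D_solution"] / out["median_D_nucleus"]
    out["n"] = n_replicates
    return out


#: FCS study conditions: N = 10 apparent particles, tau_D = 1 ms, 20%
#: triplet at the fixed 4 us lifetime, 30-s traces binned at 10 us.
FCS_STUDY = dict(N=10.0, tau_D=1e-3, w0=0.25, T=0.2)
#: Fit window: above twice the Brownian propagation step, below the lag
#: region where G has decayed into the noise floor.
FCS_FIT_WINDOW = (2e-4, 2e-2)
FCS_REF_WINDOW = (8e-6, 8e-4)


def fcs_reference_calibration(seed: int = 0, D_ref: float = 400.0,
                              kappa: float = 5.0, n_spots: int = 3) -> dict:
    """Calibrate the effective volume from a simulated reference dye.

    The reference (D = 400 um^2/s, the faster of the two calibration dyes)
    is recorded on three spots — the same per-measurement replication used
    for cellular FCS — for 20 s each at 4 us bins so its ~39 us diffusion
    time is resolved.  w0 and V_eff follow from the median fitted tau_D
    (w0 errors enter V_eff cubed, so the median over spots matters).
    """
    w0 = FCS_STUDY["w0"]
    taus = []
    for i in range(n_spots):
        gt = FcsGroundTruth(n_particles_mean=5.0, D_true=D_ref, w0=w0,
                            brightness=2.0, bin_time=4e-6, duration=20.0,
                            triplet_fraction=0.0, seed=_subseed(seed, 300007, i))
        fit = fit_acf(autocorrelate(generate_fcs_trace(gt)),
                      lag_range=FCS_REF_WINDOW)
        taus.append(fit.tau_D)
    median_fit = FcsFit(N=5.0, tau_D=float(np.median(taus)), T=0.0,
                        tau_T=4e-6, r2=1.0)
    w0_hat, v_eff = calibrate_volume(median_fit, D_ref, kappa=kappa)
    v_eff_true = math.pi ** 1.5 * w0 ** 3 * kappa * 1e-15
    return {"w0_um": w0_hat, "effective_volume_l": v_eff,
            "true_effective_volume_l": v_eff_true,
            "tau_D_ref": median_fit.tau_D, "n_spots": n_spots}


def fcs_study(n_replicates: int = 100, seed: int = 0) -> dict:
    """Particle number, diffusion time and concentration from 30-s traces.

    Plants N = 10, tau_D = 1 ms and a 20% triplet fraction; fits the 2D
    diffusion + triplet model with tau_T fixed at 4 us and converts the
    median N into a molar concentration through the reference-calibrated
    effective volume.
    """
    p = FCS_STUDY
    D_true = p["w0"] ** 2 / (4.0 * p["tau_D"])
    Ns, taus = [], []
    for i in range(n_replicates):
        gt = FcsGroundTruth(n_particles_mean=p["N"], D_true=D_true,
                            w0=p["w0"], triplet_fraction=p["T"],
                            seed=_subseed(seed, 400009, i))
        fit = fit_acf(autocorrelate(generate_fcs_trace(gt)),
                      lag_range=FCS_FIT_WINDOW)
        Ns.append(fit.N)
        taus.append(fit.tau_D)
    cal = fcs_reference_calibration(seed=seed)
    median_N = float(np.median(Ns))
    conc = median_N / (cal["effective_volume_l"] * AVOGADRO)
    conc_true = p["N"] / (cal["true_effective_volume_l"] * AVOGADRO)
    return {"median_N": median_N, "median_tau_D": float(np.median(taus)),
            "true_N": p["N"], "true_tau_D": p["tau_D"],
            "concentration_molar": conc, "true_concentration_molar": conc_true,
            "n": n_replicates, **{f"cal_{k}": v for k, v in cal.items()}}


def _segmentation_field(seed: int, n_nuclei: int = 30,
                        image_shape=(1200, 1200)) -> tuple[SceneSpec, int]:
    """One DAPI field: 30 nuclei (25-100 px) incl. touching pairs, plus up
    to two sub-gate specks that the size filter must reject."""
    rng = np.random.default_rng(seed)
    nuclei = random_nuclei(n_nuclei, image_shape, diameter_range=(25, 100),
                           rng=rng, n_touching_pairs=5)
    n_specks = 0
    for corner in ((25.0, 25.0), (25.0, image_shape[1] - 25.0),
                   (image_shape[0] - 25.0, 25.0)):
        if n_specks >= 2:
            break
        clear = all(math.hypot(corner[0] - n.center[0], corner[1] - n.center[1])
                    > max(n.semi_axes) + 12 for n in nuclei)
        if clear:
            nuclei = list(nuclei) + [NucleusSpec((corner[0], corner[1]), (5.0, 5.0))]
            n_specks += 1
    spec = SceneSpec(image_shape=image_shape, nuclei=nuclei,
                     compartment_concentrations={
                         "dapi": {"nucleus": 4e-7, "cytosol": 5e-8}},
                     counts_per_molar=5e8, background_counts=0.5,
                     bit_depth=8, overlap_tolerance=0.5, seed=seed)
    return spec, n_specks


def segmentation_study(n_fields: int = 20, seed: int = 0) -> dict:
    """Object-count accuracy, sub-gate rejection and Otsu-oracle agreement
    over synthetic DAPI fields with touching nuclei."""
    from skimage.filters import threshold_multiotsu
    from skimage.measure import regionprops

    total_true = total_found = 0
    specks_planted = specks_leaked = 0
    otsu_matches = 0
    for f in range(n_fields):
        spec, n_specks = _segmentation_field(_subseed(seed, 500029, f))
        scene = generate_scene(spec)
        img = scene.images["dapi"]
        lm = segment_nuclei(img)
        total_true += 30
        total_found += lm.n_objects
        specks_planted += n_specks
        for prop in regionprops(lm.labels):
            if prop.equivalent_diameter_area < 20.0:
                specks_leaked += 1
        # exhaustive three-class split must match the independent oracle
        mine = otsu_three_class(img)
        theirs = threshold_multiotsu(img, classes=3)
        flat = img.ravel().astype(float)

        def wcv(t1, t2):
            tot = 0.0
            for m in (flat <= t1, (flat > t1) & (flat <= t2), flat > t2):
                if m.any():
                    tot += float(((flat[m] - flat[m].mean()) ** 2).sum())
            return tot

        if math.isclose(wcv(*mine), wcv(*theirs), rel_tol=1e-12):
            otsu_matches += 1
    return {"count_accuracy_pct": 100.0 * total_found / total_true,
            "sub_gate_objects_leaked": specks_leaked,
            "specks_planted": specks_planted,
            "otsu_oracle_agreement": otsu_matches, "n_fields": n_fields}


def knockdown_study(seed: int = 0, n_cells: int = 100,
                    output_dir: str = "scratch/knockdown_study") -> dict:
    """Three-dose microinjection experiment at 50 cells per group.

    Doses 1e3/1e4/1e5 injected copies map to knockdown factors 1.0/0.8/0.4;
    reports the estimated relative target levels and the monotonicity flag.
    """
    from .pipeline import run_microinjection_pipeline

    cfg = RunConfig(seed=_subseed(seed, 600011), bit_depth=8, output_dir=output_dir)
    table, _ = run_microinjection_pipeline(cfg, n_cells=n_cells)
    levels = dict(zip(table["copies"], table["relative_level"]))
    return {"relative_levels": {f"{int(k):d}": float(v)
                                for k, v in levels.items()},
            "true_factors": {"1000": 1.0, "10000": 0.8, "100000": 0.4},
            "monotone": bool(table.attrs["monotone"]),
            "n_cells_per_dose": n_cells}
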