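"""Standard validation experiments on synthetic ground truth.

Each function here sets up one of the package's reference study conditions —
the same-protein negative control, planted-compartment parameter recovery
over a fold x length grid, channel-swap/scale invariance checks, the
colocalization battery and the scenario presets — runs the package on it,
and returns the measured quantities.  The test suite asserts thresholds on
these numbers; ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np

from .compartments import (
    ENRICHMENT_OF_DOMINANT,
    EXCLUSION_OF_OTHER,
    analyze_cell,
    detect_compartments,
    ratio_profile,
    smooth_ratio,
)
from .coloc import coloc_score, fft_highpass
from .datatypes import ProfilePair, Roi
from .presets import list_presets, load_preset
from .simulate import PlantedCompartment, SimulationSpec, make_coloc_scene, make_profile_pair
from .trace import sample_profile

__all__ = [
    "same_protein_null",
    "planted_recovery",
    "attribution_on_noiseless_plants",
    "bruteforce_segments",
    "oracle_equivalence",
    "swap_scale_invariance",
    "coloc_battery",
    "preset_outcomes",
]

_SEED_MOD = 2**31


# ---------------------------------------------------------------------------
# criterion experiments
# ---------------------------------------------------------------------------


def same_protein_null(
    seed: int,
    total_length_um: float = 1000.0,
    n_profiles: int = 20,
    noise_sd_frac: float = 0.03,
) -> dict:
    """Negative control: same protein in both channels, independent 3% noise.

    Both channels report the same underlying decoration, so no compartment
    should be detected anywhere along >= 1 mm of simulated network.
    """
    per_len = total_length_um / n_profiles
    profiles = []
    for i in range(n_profiles):
        p, _ = make_profile_pair(
            [], per_len, noise_sd_frac=noise_sd_frac, seed=(seed * 7919 + i) % _SEED_MOD,
            path_id=i,
        )
        profiles.append(p)
    cell = analyze_cell("same_protein_null", profiles)
    return {
        "n_compartments": len(cell.compartments),
        "total_length_um": cell.total_analyzed_length_um,
    }


def planted_recovery(
    seed: int,
    folds: tuple[float, ...] = (1.3, 1.5, 2.0, 3.0),
    lengths_um: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    noise_sd_frac: float = 0.03,
    profile_length_um: float = 60.0,
    step_um: float = 0.03,
) -> dict:
    """Plant one compartment per profile over a fold x length grid; recover it.

    Each (fold, length) combination lives centered on its own profile;
    detection runs with pooled per-cell normalization.  Returns recall, the
    mean absolute boundary error in samples, and the mean relative error of
    the measured enrichment against the planted (fold - 1) x 100%.
    """
    combos = [(f, l) for f in folds for l in lengths_um]
    profiles, truths = [], []
    for i, (fold, length) in enumerate(combos):
        mode = "enrich_ch1" if i % 2 == 0 else "enrich_ch2"
        c = PlantedCompartment(
            path_id=i,
            start_um=(profile_length_um - length) / 2.0,
            end_um=(profile_length_um + length) / 2.0,
            mode=mode,
            fold=fold,
        )
        p, _ = make_profile_pair(
            [c],
            profile_length_um,
            step_um=step_um,
            noise_sd_frac=noise_sd_frac,
            seed=(seed * 6151 + i) % _SEED_MOD,
            path_id=i,
        )
        profiles.append(p)
        truths.append(c)
    cell = analyze_cell("recovery", profiles)
    by_path: dict[int, list] = {}
    for comp in cell.compartments:
        by_path.setdefault(comp.path_id, []).append(comp)

    matched = 0
    boundary_errs, enrich_rel_errs = [], []
    for true in truths:
        dom = true.dominant_channel()
        cands = [
            c
            for c in by_path.get(true.path_id, [])
            if c.dominant_channel == dom
            and min(c.end_um, true.end_um) > max(c.start_um, true.start_um)
        ]
        if not cands:
            continue
        best = max(
            cands, key=lambda c: min(c.end_um, true.end_um) - max(c.start_um, true.start_um)
        )
        matched += 1
        boundary_errs.append(
            0.5
            * (abs(best.start_um - true.start_um) + abs(best.end_um - true.end_um))
            / step_um
        )
        true_pct = (true.ratio_fold() - 1.0) * 100.0
        enrich_rel_errs.append(abs(best.enrichment_pct - true_pct) / true_pct)
    return {
        "n_planted": len(truths),
        "n_matched": matched,
        "recall": matched / len(truths),
        "boundary_error_samples_mean": float(np.mean(boundary_errs)) if boundary_errs else None,
        "enrichment_rel_error_mean": float(np.mean(enrich_rel_errs)) if enrich_rel_errs else None,
        "n_detected_total": len(cell.compartments),
    }


def attribution_on_noiseless_plants(
    seed: int = 0, fold: float = 2.0, profile_length_um: float = 60.0
) -> dict:
    """Attribution accuracy on noiseless enrich-only and deplete-only plants.

    Pure enrichment of the dominant channel must be attributed to enrichment;
    pure depletion of the other channel to exclusion.
    """
    cases = [
        ("enrich_ch1", ENRICHMENT_OF_DOMINANT),
        ("enrich_ch2", ENRICHMENT_OF_DOMINANT),
        ("deplete_ch2", EXCLUSION_OF_OTHER),
        ("deplete_ch1", EXCLUSION_OF_OTHER),
    ]
    n_correct = n_total = 0
    for i, (mode, expected) in enumerate(cases):
        c = PlantedCompartment(
            path_id=i, start_um=28.0, end_um=32.0, mode=mode, fold=fold
        )
        p, _ = make_profile_pair(
            [c], profile_length_um, noise_sd_frac=0.0, seed=seed, path_id=i
        )
        cell = analyze_cell(f"attr_{mode}", [p])
        for comp in cell.compartments:
            n_total += 1
            n_correct += comp.attribution == expected
    return {"n_total": n_total, "n_correct": n_correct,
            "accuracy": n_correct / n_total if n_total else None}


# ---------------------------------------------------------------------------
# brute-force oracle for run detection
# ---------------------------------------------------------------------------


def bruteforce_segments(
    n: np.ndarray,
    threshold: float,
    min_run_samples: int,
    smoothing_window: int,
) -> list[tuple[str, int, int]]:
    """Independent maximal-run scan over a normalized-ratio series.

    Plain-python reference: geometric moving average with edge replication,
    then a linear scan enumerating every maximal supra-threshold run.
    Returns (dominant, first_index, last_index) tuples sorted like the
    detector's output.
    """
    n = np.asarray(n, dtype=float)
    size = len(n)
    logs = [float(np.log(v)) for v in n]
    w = int(smoothing_window)
    ns = []
    for i in range(size):
        lo = i - (w // 2)
        hi = lo + w
        acc = 0.0
        for j in range(lo, hi):
            acc += logs[min(max(j, 0), size - 1)]
        ns.append(np.exp(acc / w))
    out = []
    for dominant, test in (
        ("RBP1", lambda v: v > 1.0 + threshold),
        ("RBP2", lambda v: 1.0 / v > 1.0 + threshold),
    ):
        i = 0
        while i < size:
            if test(ns[i]):
                j = i
                while j + 1 < size and test(ns[j + 1]):
                    j += 1
                if j - i + 1 >= min_run_samples:
                    out.append((dominant, i, j))
                i = j + 1
            else:
                i += 1
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def _random_ratio_profiles(seed: int, n_profiles: int, length: int = 300):
    """Random i.i.d. lognormal normalized-ratio series with occasional shifts."""
    rng = np.random.default_rng(seed)
    for _ in range(n_profiles):
        logn = rng.normal(0.0, 0.12, size=length)
        # plant a few block shifts so supra-threshold runs actually occur
        for _ in range(rng.integers(0, 4)):
            a = int(rng.integers(0, length - 20))
            b = a + int(rng.integers(5, 60))
            logn[a:b] += rng.uniform(-0.5, 0.5)
        yield np.exp(logn)


def oracle_equivalence(
    seed: int, n_profiles: int = 1000, smoothing_window: int = 5
) -> dict:
    """Compare detect_compartments to the brute-force scan on random profiles."""
    step = 0.03
    mismatches = 0
    n_segments = 0
    for k, n in enumerate(_random_ratio_profiles(seed, n_profiles)):
        from .compartments import RatioProfile

        pos = (np.arange(len(n)) + 0.5) * step
        rp = RatioProfile(
            positions_um=pos, r=n, n=n, epsilon1=0.0, epsilon2=0.0,
            step_um=step, path_id=k, mean_i1=1.0, mean_i2=1.0,
        )
        got = [
            (
                c.dominant_channel,
                int(round((c.start_um + step / 2.0) / step - 0.5)),
                int(round((c.end_um - step / 2.0) / step - 0.5)),
            )
            for c in detect_compartments(rp, smoothing_window=smoothing_window)
        ]
        want = bruteforce_segments(n, 0.20, 5, smoothing_window)
        n_segments += len(want)
        if got != want:
            mismatches += 1
    return {"n_profiles": n_profiles, "n_segments": n_segments, "mismatches": mismatches}


# ---------------------------------------------------------------------------
# symmetry / invariance
# ---------------------------------------------------------------------------


def _random_profile_pair(rng: np.random.Generator, path_id: int) -> ProfilePair:
    length_um = 30.0
    planted = []
    pos = 2.0
    while pos < length_um - 4.0 and rng.random() < 0.6:
        seg = float(rng.uniform(0.3, 3.0))
        planted.append(
            PlantedCompartment(
                path_id=path_id,
                start_um=pos,
                end_um=pos + seg,
                mode=str(rng.choice(["enrich_ch1", "enrich_ch2", "deplete_ch1", "deplete_ch2"])),
                fold=float(rng.uniform(1.2, 3.0)),
            )
        )
        pos += seg + float(rng.uniform(1.0, 5.0))
    p, _ = make_profile_pair(
        planted,
        length_um,
        noise_sd_frac=0.05,
        seed=int(rng.integers(0, _SEED_MOD)),
        path_id=path_id,
    )
    return p


def _comp_key(c) -> tuple:
    return (c.start_um, c.end_um, c.dominant_channel)


def swap_scale_invariance(seed: int, n_profiles: int = 200) -> dict:
    """Exactness of channel-swap symmetry and per-channel scale invariance.

    Swapping I1 and I2 must map every RBP1-dominant compartment to an
    RBP2-dominant one with identical boundaries, enrichment and attribution;
    multiplying either channel by a positive constant must leave everything
    unchanged.  Counts profiles where either fails.
    """
    rng = np.random.default_rng(seed)
    swap_mismatch = scale_mismatch = 0
    for k in range(n_profiles):
        p = _random_profile_pair(rng, k)
        a = float(rng.uniform(0.2, 5.0))
        b = float(rng.uniform(0.2, 5.0))
        swapped = ProfilePair(
            path_id=k, positions_um=p.positions_um, i_rbp1=p.i_rbp2.copy(),
            i_rbp2=p.i_rbp1.copy(), step_um=p.step_um,
        )
        scaled = ProfilePair(
            path_id=k, positions_um=p.positions_um, i_rbp1=a * p.i_rbp1,
            i_rbp2=b * p.i_rbp2, step_um=p.step_um,
        )

        def _detect(pp):
            rp = ratio_profile(pp)
            cs = detect_compartments(rp)
            from .compartments import attribute_compartment

            for c in cs:
                attribute_compartment(c, pp, rp=rp)
            return cs

        ref = _detect(p)
        sw = _detect(swapped)
        sc = _detect(scaled)
        flip = {"RBP1": "RBP2", "RBP2": "RBP1"}
        ref_sw = sorted(
            ((c.start_um, c.end_um, flip[c.dominant_channel]) for c in ref)
        )
        if ref_sw != sorted(_comp_key(c) for c in sw) or not np.allclose(
            sorted(c.enrichment_pct for c in ref),
            sorted(c.enrichment_pct for c in sw),
            rtol=1e-9,
        ) or sorted(c.attribution for c in ref) != sorted(c.attribution for c in sw):
            swap_mismatch += 1
        if sorted(map(_comp_key, ref)) != sorted(map(_comp_key, sc)) or not np.allclose(
            sorted(c.enrichment_pct for c in ref),
            sorted(c.enrichment_pct for c in sc),
            rtol=1e-9,
        ):
            scale_mismatch += 1
    return {
        "n_profiles": n_profiles,
        "swap_mismatches": swap_mismatch,
        "scale_mismatches": scale_mismatch,
    }


# ---------------------------------------------------------------------------
# colocalization battery
# ---------------------------------------------------------------------------


def coloc_battery(seed: int) -> dict:
    """Self-correlation, independence null, transfer response, co-fraction trend."""
    rng = np.random.default_rng(seed)
    px_nm = 30.0

    # channel against itself on a structured image
    spec = SimulationSpec(seed=int(rng.integers(0, _SEED_MOD)), background_level=50.0)
    img, _ = make_coloc_scene(1.0, spec)
    roi = Roi(np.ones(img.shape, dtype=bool))
    self_rho = coloc_score(img.ch1, img.ch1, roi, px_nm).spearman_rho

    # two independent noise channels, 1e5 ROI pixels
    shape = (320, 320)  # 102,400 pixels
    a = rng.normal(size=shape)
    b = rng.normal(size=shape)
    null_rho = coloc_score(a, b, Roi(np.ones(shape, dtype=bool)), px_nm).spearman_rho

    # analytic transfer response at 0.5 um and 8 um periods (exact FFT bins)
    size = 512
    length_um = size * px_nm / 1000.0
    x_um = np.arange(size) * px_nm / 1000.0
    retention = {}
    for label, cycles in (("0.5um", 31), ("8um", 2)):
        period = length_um / cycles
        wave = np.sin(2 * np.pi * x_um / period)
        img2d = np.tile(wave, (size, 1))
        filt = fft_highpass(img2d, px_nm)
        retention[label] = float(np.ptp(filt) / np.ptp(img2d))

    # monotonicity of rho in the true co-occupancy fraction
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    rhos = []
    for i, f in enumerate(grid):
        spec = SimulationSpec(seed=(seed * 104729 + i) % _SEED_MOD, background_level=50.0)
        im, _ = make_coloc_scene(f, spec)
        rhos.append(
            coloc_score(im.ch1, im.ch2, Roi(np.ones(im.shape, dtype=bool)), px_nm).spearman_rho
        )

    # noiseless perfect co-occupancy
    spec = SimulationSpec(seed=(seed * 31 + 7) % _SEED_MOD, noise_model="none")
    im, _ = make_coloc_scene(1.0, spec)
    perfect_rho = coloc_score(
        im.ch1, im.ch2, Roi(np.ones(im.shape, dtype=bool)), px_nm
    ).spearman_rho

    return {
        "self_rho": float(self_rho),
        "null_abs_rho": float(abs(null_rho)),
        "null_n_pixels": int(np.prod(shape)),
        "retention_0p5um": retention["0.5um"],
        "retention_8um": retention["8um"],
        "co_fraction_grid": grid,
        "rho_by_co_fraction": [float(r) for r in rhos],
        "perfect_overlap_rho": float(perfect_rho),
    }


# ---------------------------------------------------------------------------
# presets end to end
# ---------------------------------------------------------------------------


def preset_outcomes(names: list[str] | None = None) -> dict:
    """Render each scenario preset and run the full profile->detect chain."""
    out = {}
    for name in names or list_presets():
        img, gt = load_preset(name)
        profiles = [sample_profile(img, p) for p in gt.paths]
        cell = analyze_cell(name, profiles, min_total_length_um=50.0)
        enrich = [c.enrichment_pct for c in cell.compartments]
        attrs = [c.attribution for c in cell.compartments]
        out[name] = {
            "n_compartments": len(cell.compartments),
            "median_enrichment_pct": float(np.median(enrich)) if enrich else None,
            "exclusion_fraction": (
                attrs.count(EXCLUSION_OF_OTHER) / len(attrs) if attrs else None
            ),
            "total_length_um": cell.total_analyzed_length_um,
        }
    return out
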