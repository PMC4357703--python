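"""Seeded generators emulating the three tweezers experiment families.

The generators produce (i) metastable and equilibrium force-extension
curves of a 24-kb dsDNA titrated with a bis-intercalator, (ii) kinetic
traces of the three-state model under wash-off / force-jump /
intercalation protocols, and (iii) paired unzip/rezip force-distance
curves of a hairpin with planted ligand-binding events.  Every generator
takes a seed and emits its ground-truth parameters alongside the data so
that recovery can be scored.

Default noise emulates the instrument: 0.1 pN force resolution and
~2 nm distance scatter on 1-kHz data filtered to 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingParams, TitrationTable, mgvh_fraction
from .constants import BP_RISE
from .footprint import Fdc, HairpinConstruct, UnzipTheory, predict_equilibrium_fdc
from .kinetics import (
    KineticTrace,
    ThreeStateModel,
    equilibrium_occupancy,
    fractional_elongation,
    simulate_protocol,
    thiocoraline_model,
)
from .polymer import ForceExtensionCurve, WlcParams, wlc_extension

__all__ = [
    "SimulationRecipe",
    "DEFAULT_CONCENTRATIONS_NM",
    "gen_titration_fecs",
    "gen_titration_table",
    "gen_kinetic_trace",
    "gen_hairpin",
    "gen_unzip_pair",
]

#: Nine ligand concentrations spanning the experimental 0-1000 nM range
#: (three decades plus the naked-DNA reference).
DEFAULT_CONCENTRATIONS_NM = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 600.0, 1000.0)

#: Template size of the stretching construct (half lambda-DNA), bp.
DEFAULT_N_BP = 24000

DEFAULT_FORCE_SD = 0.1  # pN
DEFAULT_DISTANCE_SD = 2.0  # nm


@dataclass
class SimulationRecipe:
    """Reproducible description of one synthetic experiment."""

    kind: str  # titration_fec | kinetic_trace | unzip_pair
    params: dict = field(default_factory=dict)
    noise_force_sd: float = DEFAULT_FORCE_SD
    noise_distance_sd: float = DEFAULT_DISTANCE_SD
    seed: int | None = None

    def __post_init__(self):
        if self.noise_force_sd < 0 or self.noise_distance_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def _naked_wlc(N_bp=DEFAULT_N_BP):
    return WlcParams(l0=N_bp * BP_RISE)


def gen_titration_fecs(
    concentrations=DEFAULT_CONCENTRATIONS_NM,
    binding: BindingParams | None = None,
    wlc: WlcParams | None = None,
    model: ThreeStateModel | None = None,
    N_bp=DEFAULT_N_BP,
    forces=None,
    equilibrium=False,
    noise_distance_sd=DEFAULT_DISTANCE_SD,
    seed=None,
):
    """Force-extension curves across a ligand titration.

    Metastable curves (default) freeze the zero-force equilibrium
    binding fraction from the McGhee-von Hippel isotherm and stretch an
    extensible WLC of the correspondingly elongated contour.  With
    ``equilibrium=True`` the occupancy re-equilibrates at every force
    through the three-state model, which lengthens the contour as force
    grows — the signature that depresses apparent persistence length in
    naive fits.

    Returns ``(curves, truth)``: a dict mapping concentration to
    :class:`ForceExtensionCurve` and the ground-truth parameters.
    """
    rng = np.random.default_rng(seed)
    if binding is None:
        binding = BindingParams(Kd=77.0, n=3.84)
    if wlc is None:
        wlc = _naked_wlc(N_bp)
    if model is None:
        model = thiocoraline_model()
    if forces is None:
        forces = np.linspace(0.25, 40.0, 200)
    forces = np.asarray(forces, dtype=float)

    curves = {}
    truth = {"binding": binding, "wlc": wlc, "concentrations": tuple(concentrations), "seed": seed}
    for L in concentrations:
        if equilibrium:
            ext = np.empty_like(forces)
            for i, F in enumerate(forces):
                occ = equilibrium_occupancy(model, F, L)
                nu_eff = fractional_elongation(occ, model.phi) / binding.n
                wp = WlcParams(l0=wlc.l0 * (1.0 + 2.0 * nu_eff), Lp=wlc.Lp, S=wlc.S, kBT=wlc.kBT)
                ext[i] = wlc_extension(F, wp, "extensible")
        else:
            nu = mgvh_fraction(L, binding.Kd, binding.n)
            wp = WlcParams(l0=wlc.l0 * (1.0 + 2.0 * nu), Lp=wlc.Lp, S=wlc.S, kBT=wlc.kBT)
            ext = wlc_extension(forces, wp, "extensible")
        if noise_distance_sd > 0:
            ext = ext + rng.normal(0.0, noise_distance_sd, size=ext.shape)
        curves[float(L)] = ForceExtensionCurve(
            force=forces.copy(),
            extension=ext,
            direction="stretch",
            pulling_speed=1500.0,
            metadata={"ligand_nM": float(L), "equilibrium": equilibrium, "seed": seed},
        )
    return curves, truth


def gen_titration_table(
    concentrations=DEFAULT_CONCENTRATIONS_NM,
    binding: BindingParams | None = None,
    N_bp=DEFAULT_N_BP,
    noise_frac=0.02,
    n_molecules=7,
    seed=None,
) -> TitrationTable:
    """Synthetic contour-length titration with multiplicative noise.

    Contour lengths follow l0([L]) = l0_dna (1 + 2 nu([L])) with nu from
    the McGhee-von Hippel isotherm; each entry carries independent
    Gaussian noise of relative standard deviation ``noise_frac``.
    """
    rng = np.random.default_rng(seed)
    if binding is None:
        binding = BindingParams(Kd=77.0, n=3.84)
    conc = np.asarray(concentrations, dtype=float)
    l0_dna = N_bp * BP_RISE
    nu = mgvh_fraction(conc, binding.Kd, binding.n)
    l0_true = l0_dna * (1.0 + 2.0 * nu)
    l0_obs = l0_true * (1.0 + rng.normal(0.0, noise_frac, size=conc.shape))
    df = pd.DataFrame(
        {
            "conc_nM": conc,
            "l0_nm": l0_obs,
            "sd_nm": noise_frac * l0_true,
            "n_molecules": n_molecules,
        }
    )
    return TitrationTable(data=df, N_bp=N_bp, metadata={"seed": seed, "truth": binding})


def gen_kinetic_trace(
    model: ThreeStateModel | None = None,
    protocol="washoff",
    force=12.0,
    ligand_nM=100.0,
    force_initial=2.0,
    binding: BindingParams | None = None,
    wlc: WlcParams | None = None,
    as_extension=False,
    noise_sd=0.01,
    seed=None,
    **kwargs,
) -> KineticTrace:
    """Kinetic trace of one constant-force protocol.

    Delegates to :func:`dnaclamp.kinetics.simulate_protocol`; with
    ``as_extension=True`` the fractional elongation chi is mapped onto
    molecular extension through the WLC curves of naked and saturated
    DNA at the trace force (the unique affine map with chi(U) = 0 and
    chi(B) = 1).
    """
    if model is None:
        model = thiocoraline_model()
    trace = simulate_protocol(
        model,
        protocol,
        force=force,
        ligand_nM=ligand_nM,
        force_initial=force_initial if protocol == "force_jump" else None,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )
    if as_extension:
        if binding is None:
            binding = BindingParams(Kd=77.0, n=3.84)
        if wlc is None:
            wlc = _naked_wlc()
        x_U = wlc_extension(force, wlc, "extensible")
        sat = WlcParams(l0=wlc.l0 * (1.0 + 2.0 / binding.n), Lp=wlc.Lp, S=wlc.S, kBT=wlc.kBT)
        x_B = wlc_extension(force, sat, "extensible")
        trace = KineticTrace(
            time=trace.time,
            signal=x_U + trace.signal * (x_B - x_U),
            force=trace.force,
            signal_kind="extension",
            metadata={**trace.metadata, "x_U": float(x_U), "x_B": float(x_B)},
        )
    return trace


def gen_hairpin(length=480, gc_fraction=0.5, planted_motifs=(), seed=None, **kwargs) -> HairpinConstruct:
    """Random hairpin stem with optional planted sequence motifs.

    ``planted_motifs`` is a list of (motif, position) with 1-based
    positions on the opened strand; motifs must not overlap.
    """
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    seq = list(rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at]))
    taken = []
    for motif, pos in planted_motifs:
        start = pos - 1
        if start < 0 or start + len(motif) > length:
            raise ValueError(f"motif {motif!r} at {pos} outside the stem")
        span = (start, start + len(motif))
        for lo, hi in taken:
            if span[0] < hi and lo < span[1]:
                raise ValueError("planted motifs overlap")
        taken.append(span)
        seq[start : start + len(motif)] = list(motif.upper())
    return HairpinConstruct(stem_sequence="".join(seq), **kwargs)


def gen_unzip_pair(
    construct: HairpinConstruct,
    planted_events=(),
    dg_lig=10.0,
    noise_distance_sd=DEFAULT_DISTANCE_SD,
    noise_force_sd=DEFAULT_FORCE_SD,
    spacing=0.5,
    salt=0.1,
    temperature=298.0,
    rezip_artifacts=(),
    rupture_excess=6.0,
    rupture_sd=1.5,
    seed=None,
    theory: UnzipTheory | None = None,
    baseline_fdc=None,
):
    """Paired unzip/rezip FDCs with planted ligand-binding events.

    Each planted event is a step position j (1-based, clamping base
    pairs j and j+1) or a ``(j, dG)`` pair; the ligand adds ``dG`` (kBT)
    to the opening cost of base pair j on the unzipping sweep only —
    unzipping strips the ligand, so the rezip sweep is ligand-free.
    Ligand removal is a kinetic rupture: the fork stalls at the clamp
    until the force exceeds the local unzipping baseline by a random
    excess of ``rupture_excess`` +- ``rupture_sd`` pN (seeded), as
    observed for rupture peaks riding the sawtooth.
    ``rezip_artifacts`` optionally plants kinetic-blocking states that
    lower the refolding cost on the rezip sweep, emulating transient
    misfolded structures; these must not be reported as binding.

    Returns ``(unzip, rezip, truth)``.
    """
    rng = np.random.default_rng(seed)
    if theory is None:
        theory = UnzipTheory.from_construct(construct, salt=salt, temperature=temperature)
    N = construct.N
    if planted_events and baseline_fdc is None:
        baseline_fdc = predict_equilibrium_fdc(theory, spacing=4.0)
    extra_unzip = np.zeros(N)
    planted = []
    blocks = []
    for ev in planted_events:
        j, dg = ev if isinstance(ev, (tuple, list)) else (ev, dg_lig)
        if not 1 <= j <= N - 1:
            raise ValueError(f"event step {j} outside the stem")
        extra_unzip[j - 1] += dg  # block opening of the first clamped bp
        near = np.abs(baseline_fdc.n - j) <= 15
        local_force = float(np.mean(baseline_fdc.force[near])) if near.any() else float(
            np.mean(baseline_fdc.force)
        )
        f_rupture = local_force + rng.normal(rupture_excess, rupture_sd)
        blocks.append((int(j), float(f_rupture)))
        planted.append((int(j), float(dg), float(f_rupture)))
    extra_rezip = np.zeros(N)
    for j, dg in rezip_artifacts:
        if not 1 <= j <= N - 1:
            raise ValueError(f"artifact step {j} outside the stem")
        extra_rezip[j - 1] -= dg

    unzip = predict_equilibrium_fdc(
        theory,
        dg_extra=extra_unzip if planted else None,
        spacing=spacing,
        direction="unzip",
        mode="sample",
        rng=rng,
        kinetic_blocks=blocks,
    )
    rezip = predict_equilibrium_fdc(
        theory,
        dg_extra=extra_rezip if len(rezip_artifacts) else None,
        positions=unzip.distance,
        direction="rezip",
        mode="sample",
        rng=rng,
    )
    out = []
    for fdc, direction in ((unzip, "unzip"), (rezip, "rezip")):
        d = fdc.distance + rng.normal(0.0, noise_distance_sd, size=fdc.distance.shape)
        f = fdc.force + rng.normal(0.0, noise_force_sd, size=fdc.force.shape)
        out.append(
            Fdc(
                distance=d,
                force=f,
                direction=direction,
                metadata={"seed": seed, "planted_events": planted},
            )
        )
    truth = {
        "planted_events": planted,
        "rezip_artifacts": tuple(rezip_artifacts),
        "seed": seed,
        "noise_distance_sd": noise_distance_sd,
        "noise_force_sd": noise_force_sd,
    }
    return out[0], out[1], truth
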