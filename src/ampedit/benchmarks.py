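"""Simulation studies evaluating the pipeline against its own generator.

Each study builds synthetic experiments with :mod:`ampedit.simulate`, runs
the full analysis, and reports summary statistics: editing-rate recovery,
false-discovery behavior of the translocation test under a null with
symmetric chimeric noise, spike-in fusion detection across a dilution
series, label-swap robustness of the classifier, and the exactness of a
noise-free round trip. All studies are deterministic given their seed
(child seeds are spawned from one numpy SeedSequence).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .pipeline import RunConfig, analyze_reads
from .simulate import EditingSpectrum, FusionSpec, SimSpec, generate_random_panel, simulate_experiment


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def rate_recovery_study(
    rates: tuple[float, ...] = (0.001, 0.01, 0.1),
    depth: int = 50_000,
    n_seeds: int = 20,
    amplicon_len: int = 240,
    seed: int = 0,
) -> dict[float, float]:
    """Mean relative error of the recovered editing activity per true rate.

    One single-locus panel; shared treatment/mock indel noise at half the
    editing rate per read (spread uniformly over the amplicon).
    """
    panel = generate_random_panel(1, amplicon_len=amplicon_len, seed=seed)
    out: dict[float, float] = {}
    seeds = _child_seeds(seed + 1, n_seeds * len(rates))
    k = 0
    for rate in rates:
        errs = []
        for _ in range(n_seeds):
            spec = SimSpec(
                panel=panel, depth_tx=depth, depth_m=depth,
                editing_rate=rate,
                indel_noise_rate=(rate / 2.0) / amplicon_len,
                sub_rate=0.0,
                seed=seeds[k],
            )
            k += 1
            sim = simulate_experiment(spec)
            result = analyze_reads(sim.tx_reads, sim.m_reads, panel)
            est = result.site_results[panel[0].site_id].activity
            errs.append(abs(est - rate) / rate)
        out[rate] = float(np.mean(errs))
    return out


def null_fdr_study(
    n_sims: int = 200,
    n_sites: int = 3,
    depth: int = 800,
    editing_rate: float = 0.05,
    chimera_rate: float = 0.002,
    seed: int = 0,
) -> float:
    """Fraction of null experiments reporting any significant translocation.

    No true fusions; chimeric reads are injected at the same expected rate
    in treatment and mock (PCR-artifact model), so every significant pair
    is a false discovery. Sites carry real editing so that pairs are
    actually tested.
    """
    panel = generate_random_panel(n_sites, seed=seed)
    seeds = _child_seeds(seed + 1, n_sims)
    hits = 0
    for s in seeds:
        spec = SimSpec(
            panel=panel, depth_tx=depth, depth_m=depth,
            editing_rate=editing_rate, chimera_noise_rate=chimera_rate,
            seed=s,
        )
        sim = simulate_experiment(spec)
        result = analyze_reads(sim.tx_reads, sim.m_reads, panel)
        if any(t.significant for t in result.translocations):
            hits += 1
    return hits / n_sims


def spike_in_study(
    fractions: tuple[float, ...] = (0.0, 0.0016, 0.016, 0.16),
    depth: int = 50_000,
    editing_rate: float = 0.05,
    seed: int = 0,
) -> dict[float, bool]:
    """Dilution series of a synthetic fusion construct between two sites.

    Returns, per spiked fraction of the site depth, whether the spiked pair
    is reported significant; the 0 fraction is the un-spiked control.
    """
    panel = generate_random_panel(2, seed=seed)
    pair = tuple(sorted((panel[0].site_id, panel[1].site_id)))
    seeds = _child_seeds(seed + 1, len(fractions))
    out: dict[float, bool] = {}
    for frac, s in zip(fractions, seeds):
        fusions = [FusionSpec(panel[0].site_id, panel[1].site_id, 1, frac)] if frac else []
        spec = SimSpec(
            panel=panel, depth_tx=depth, depth_m=depth,
            editing_rate=editing_rate, fusions=fusions, seed=s,
        )
        sim = simulate_experiment(spec)
        result = analyze_reads(sim.tx_reads, sim.m_reads, panel)
        sig = {
            tuple(sorted((t.site_a, t.site_b)))
            for t in result.translocations
            if t.significant
        }
        out[frac] = pair in sig
    return out


def label_swap_study(
    n_experiments: int = 20,
    depth: int = 1500,
    editing_rate: float = 0.02,
    seed: int = 0,
) -> tuple[int, int]:
    """Total edit-classified treatment reads with correct vs swapped labels.

    Swapping the treatment and mock roles removes the asymmetry the edit
    model keys on, so edit calls should all but vanish.
    """
    panel = generate_random_panel(2, seed=seed)
    seeds = _child_seeds(seed + 1, n_experiments)
    correct = swapped = 0
    for s in seeds:
        spec = SimSpec(
            panel=panel, depth_tx=depth, depth_m=depth,
            editing_rate=editing_rate, sub_rate=1e-3,
            indel_noise_rate=2e-5, seed=s,
        )
        sim = simulate_experiment(spec)
        fwd = analyze_reads(sim.tx_reads, sim.m_reads, panel)
        rev = analyze_reads(sim.m_reads, sim.tx_reads, panel)
        correct += sum(r.edited_reads for r in fwd.site_results.values())
        swapped += sum(r.edited_reads for r in rev.site_results.values())
    return correct, swapped


def roundtrip_study(
    depth: int = 3000,
    rates: tuple[float, ...] = (0.02, 0.005, 0.05),
    fusion_fraction: float = 0.005,
    seed: int = 0,
) -> dict:
    """Noise-free end-to-end run: exact truth recovery.

    With zero sequencing noise the pipeline must report exactly the true
    edited-read count at every site, flag exactly the injected fusion pair
    as significant, and invent no others.
    """
    panel = generate_random_panel(3, seed=seed)
    rate_map = {s.site_id: r for s, r in zip(panel, rates)}
    spiked = (panel[0].site_id, panel[1].site_id)
    spec = SimSpec(
        panel=panel, depth_tx=depth, depth_m=depth,
        editing_rate=rate_map, sub_rate=0.0, indel_noise_rate=0.0,
        fusions=[FusionSpec(spiked[0], spiked[1], 1, fusion_fraction)],
        seed=seed + 1,
    )
    sim = simulate_experiment(spec)
    result = analyze_reads(sim.tx_reads, sim.m_reads, panel)
    count_errors = {
        sid: abs(result.site_results[sid].edited_reads - sim.truth.edited_counts[sid])
        for sid in rate_map
    }
    sig_pairs = {
        tuple(sorted((t.site_a, t.site_b)))
        for t in result.translocations
        if t.significant
    }
    expected_pair = tuple(sorted(spiked))
    return {
        "max_edited_count_error": max(count_errors.values()),
        "detected_pairs": sig_pairs,
        "expected_pair_detected": expected_pair in sig_pairs,
        "false_pairs": len(sig_pairs - {expected_pair}),
        "n_reads": len(sim.tx_reads) + len(sim.m_reads),
    }
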