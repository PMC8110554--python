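"""End-to-end parameter-recovery experiments on synthetic cohorts.

Each experiment plants a known effect with the generators in
:mod:`synei.synthetic`, runs the corresponding analysis pipeline on the raw
synthetic data, and reports how well the planted truth is recovered.  They
double as the package's self-validation: if a pipeline stage is broken, the
planted parameters stop coming back.
"""

from __future__ import annotations

import numpy as np

from . import ephys as ep
from . import fdt
from . import synthetic as sy
from . import transcriptome as tx
from .stats import GroupSample, compare_groups, wilcoxon_ranksum

__all__ = [
    "subject_anatomical_ratio",
    "anatomical_recovery_experiment",
    "ephys_bias_experiment",
    "gphn_wilcoxon_power",
]


def subject_anatomical_ratio(inh_spread_factor: float,
                             seed: int | np.random.SeedSequence,
                             n_stacks: int = 3,
                             base_spread: float = 16.0,
                             cfg: fdt.DetectionConfig | None = None) -> float:
    """Anatomical E/I peak ratio for one synthetic subject.

    The subject is imaged as ``n_stacks`` independent stacks whose
    inhibitory-channel intensity spread is ``inh_spread_factor`` times the
    excitatory one (planted peak ratio = the factor); puncta are pooled
    across stacks into one distribution per channel.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    stacks = []
    for child in ss.spawn(n_stacks):
        spec = sy.FdtSceneSpec(
            exc_intensity=sy.IntensityModel(spread=base_spread),
            inh_intensity=sy.IntensityModel(
                spread=base_spread * inh_spread_factor))
        stack, _ = sy.gen_fdt_stack(spec, child)
        stacks.append(stack)
    return fdt.subject_anatomical_ei(stacks, cfg=cfg)["anatomical_ei_ratio"]


def anatomical_recovery_experiment(factor: float = 1.4,
                                   n_subjects: int = 5,
                                   seeds: range | list = range(20),
                                   n_stacks: int = 3) -> dict:
    """Plant an anatomical peak-ratio elevation and recover it.

    For every seed, builds a control group (planted ratio 1) and an
    affected group (planted ratio ``factor``) of ``n_subjects`` each, runs
    the full image pipeline per subject, and tests the group difference
    with the variance-gated comparison layer.  Returns the mean recovered
    group ratio and the fraction of seeds where the affected group differs
    from control (post hoc p < 0.05).
    """
    ratios, detected = [], []
    for seed in seeds:
        root = np.random.SeedSequence(seed)
        kids = root.spawn(2 * n_subjects)
        ctrl = [subject_anatomical_ratio(1.0, kids[i], n_stacks)
                for i in range(n_subjects)]
        affected = [subject_anatomical_ratio(factor, kids[n_subjects + i],
                                             n_stacks)
                    for i in range(n_subjects)]
        ratios.append(np.mean(affected) / np.mean(ctrl))
        sample = GroupSample(values=np.array(ctrl + affected),
                             labels=np.array(["CTRL"] * n_subjects
                                             + ["AD"] * n_subjects))
        res = compare_groups(sample, "CTRL")
        detected.append(res.posthoc["AD"] < 0.05)
    return {"planted_factor": factor,
            "recovered_ratio": float(np.mean(ratios)),
            "per_seed_ratios": ratios,
            "detection_rate": float(np.mean(detected)),
            "n_seeds": len(ratios)}


def ephys_bias_experiment(true_ratio: float = 0.5,
                          noise_fraction: float = 0.01,
                          seeds: range | list = range(12)) -> dict:
    """Recover a planted electrophysiological E/I ratio across subjects.

    Noise is ``noise_fraction`` of the GABA amplitude; reports the relative
    bias of the mean subject-level E/I against the planted ratio.
    """
    means = []
    for seed in seeds:
        spec = sy.EphysSpec(gaba_amplitude=200.0, ei_ratio=true_ratio,
                            noise_sd=200.0 * noise_fraction,
                            oocyte_cv=0.05, n_applications=1)
        recs, _ = sy.gen_oocyte_traces(spec, seed)
        oocyte_ratios = []
        for rec in recs:
            by: dict[str, list] = {}
            for tr in rec.traces:
                by.setdefault(tr.agonist, []).append(ep.measure_response(tr))
            oocyte_ratios.append(ep.oocyte_ei(by["kainate"][0],
                                              by["GABA"][0]))
        means.append(ep.subject_ei(oocyte_ratios).mean_ei)
    mean_ei = float(np.mean(means))
    return {"true_ratio": true_ratio, "mean_recovered": mean_ei,
            "relative_bias": (mean_ei - true_ratio) / true_ratio,
            "n_subjects": len(means)}


def gphn_wilcoxon_power(multiplier: float = 0.6,
                        seeds: range | list = range(100),
                        alpha: float = 0.05) -> dict:
    """Power of the Wilcoxon test on the DLG4/GPHN ratio with planted GPHN loss.

    Default cohort: 8 controls vs 12 affected subjects, log-normal subject
    scatter sigma 0.25, GPHN multiplied by ``multiplier`` in the affected
    group.
    """
    hits = 0
    for seed in seeds:
        spec = sy.ExprSpec(n_genes=10,
                           multipliers={"AD": {"GPHN": multiplier}})
        mat, meta, _ = sy.gen_expression(spec, seed)
        ratios = tx.transcriptional_ei_all(mat)
        a = ratios[meta["diagnosis"] == "CTRL"].to_numpy()
        b = ratios[meta["diagnosis"] == "AD"].to_numpy()
        hits += wilcoxon_ranksum(a, b).pvalue < alpha
    return {"multiplier": multiplier, "power": hits / len(list(seeds)),
            "n_seeds": len(list(seeds))}
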