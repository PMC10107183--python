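"""Shared demo configuration for the numbered analysis drivers.

All drivers operate on the same run directory (``results/demo``), so they
can be executed in order (01..09) or all at once; each stage skips itself
when its inputs and parameters are unchanged.
"""

from pathlib import Path

from lipidsig import pipeline

RUN_DIR = Path(__file__).resolve().parent.parent / "results" / "demo"


def demo_config(stages=None) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        outdir=str(RUN_DIR),
        seed=1,
        stages=stages or list(pipeline.STAGES),
        # emulated study: 10 samples/group microarray with DE planted in the
        # lipid pathways; 7+7 crossed lipidomics design with a planted
        # genotype effect and a genotype x sex interaction; 500-person
        # single-SNP metabolome cohort
        sim={
            "n_genes": 400,
            "n_samples_per_group": 10,
            "n_de_genes": 16,
            "de_effect": 2.5,
            "interaction_effect": 1.0,
            "snp_beta": 0.4,
            "n_planted_assoc": 5,
        },
        n_perm_opls=100,
        n_boot_ewce=10000,
        n_perm_mwsl=1000,
    )


def run_stage(stage: str) -> dict:
    manifest = pipeline.run(demo_config(stages=["simulate", stage]
                                        if stage != "simulate" else ["simulate"]))
    return manifest
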