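#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the discovery setting: a 989-sample multi-cohort expression
meta-dataset with 74 candidate features (3 of them real prognostic targets,
hazard ratio 2), both survival and metastasis endpoints, plus the upstream
artifacts the filters consume — a gene-level DE result table with planted
pass/fail rows, a compartment/ortholog annotation, and tumor/wild-type
fusion-call tables in which every replicate-common event is a read-through
or homologue artifact (plus one planted genuine event for contrast).

Outputs under results/data/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from coscore import SimulationConfig, generate_cohort, generate_de_table, generate_fusion_fixture, io

OUT = Path("results/data")
SEED = 20140506

config = SimulationConfig(seed=SEED)  # study-scale defaults: 989 x 74, 3 true targets
data = generate_cohort(config)
OUT.mkdir(parents=True, exist_ok=True)
io.write_expression(data.expression, OUT / "expression.tsv")
io.write_table(data.clinical, OUT / "clinical.tsv")
io.write_table(data.truth, OUT / "truth.tsv")

true_ids = list(data.truth.loc[data.truth.is_true_target, "feature_id"])
print(f"cohort: {config.n_samples} samples x {config.n_features} features; "
      f"true targets: {', '.join(true_ids)}")
print(f"event fraction: {data.clinical.groupby('endpoint')['event'].mean().round(3).to_dict()}")

# DE table: every cohort feature passes; plus planted failures and boundary rows
rng = np.random.default_rng(SEED)
pass_rows = pd.DataFrame(
    {
        "feature_id": data.expression.columns,
        "gene_id": data.expression.columns,
        "level": "gene",
        "log2fc": rng.uniform(1.2, 6.0, config.n_features),
        "pvalue": rng.uniform(1e-6, 0.05, config.n_features),
        "fdr": rng.uniform(1e-6, 0.09, config.n_features),
        "planted_status": "pass",
    }
)
fail_rows = generate_de_table(n_pass=0, n_fail_fdr=10, n_fail_lfc=10, n_down=15, seed=SEED)
io.write_table(pd.concat([pass_rows, fail_rows], ignore_index=True), OUT / "de_gene.tsv")
print(f"DE table: {len(pass_rows)} passing + {len(fail_rows)} failing rows")

# compartment annotation: true targets always secreted/membrane with ortholog
compartments = rng.choice(["secreted", "plasma_membrane", "other"],
                          size=config.n_features, p=[0.4, 0.4, 0.2])
annotation = pd.DataFrame(
    {
        "feature_id": data.expression.columns,
        "compartment": compartments,
        "human_ortholog": [f"HUM_{f.upper()}" for f in data.expression.columns],
    }
)
annotation.loc[annotation.feature_id.isin(true_ids), "compartment"] = "secreted"
io.write_table(annotation, OUT / "annotation.tsv")

# fusion fixture mirroring the discovery outcome: artifacts only, plus one
# genuine event kept in a second fixture for contrast
for name, kwargs in (
    ("artifacts", dict(n_common=0, n_readthrough=2, n_homologue=1)),
    ("genuine", dict(n_common=1, n_readthrough=1, n_homologue=1)),
):
    mt, wt, models, expected = generate_fusion_fixture(
        n_mt_only_single=3, n_wt_shared=2, seed=SEED, **kwargs
    )
    for i, rep in enumerate(mt, 1):
        io.write_table(rep, OUT / f"fusions_{name}_mt{i}.tsv")
    for i, rep in enumerate(wt, 1):
        io.write_table(rep, OUT / f"fusions_{name}_wt{i}.tsv")
    io.write_table(models, OUT / f"gene_models_{name}.tsv")
    print(f"fusion fixture '{name}': expect {len(expected)} retained event(s)")
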