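#!/usr/bin/env python
"""Select candidate targets from the DE table.

Applies the strict up-regulation thresholds (FDR < 0.1, log2FC > 1) and then
restricts to secreted/plasma-membrane proteins with a human ortholog — the
compartments a therapeutic antibody or serum biomarker can reach.

Reads results/data/, writes results/candidates.tsv.
"""

from pathlib import Path

from coscore import io
from coscore.candidates import annotate_compartment, filter_gene_level, normalize_de_columns

DATA = Path("results/data")

de = normalize_de_columns(io.read_table(DATA / "de_gene.tsv"))
up = filter_gene_level(de)
print(f"{len(up)} of {len(de)} DE rows pass FDR < 0.1 and log2FC > 1")

annotation = io.read_table(DATA / "annotation.tsv")
candidates = annotate_compartment(up["feature_id"].astype(str), annotation)
print(f"{len(candidates)} candidates are secreted/membrane with a human ortholog")

out = up[up["feature_id"].astype(str).isin(candidates)]
io.write_table(out, Path("results/candidates.tsv"))
print(f"wrote results/candidates.tsv ({len(out)} rows)")
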