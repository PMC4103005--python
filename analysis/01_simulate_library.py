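#!/usr/bin/env python
"""Simulate the mutant-library data set: trait table, images, expression.

Generates the 181-strain (180 mutants + DK1622 wild type), 8-trait replicate
table with planted effects under the latent-copula model, a batch of
synthetic development images, and a 4-archetype expression time course —
everything downstream steps 02-06 consume — and reports the planted truth.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import tifffile

from myxphen.synthetic import (
    SimulationConfig,
    random_image_spec,
    simulate_development_image,
    simulate_expression_matrix,
    simulate_trait_table,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
parser.add_argument("--n-images", type=int, default=10)
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

seeds = np.random.SeedSequence(args.seed).spawn(3)
ints = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seeds]

cfg = SimulationConfig(rng_seed=ints[0])
table, truth = simulate_trait_table(cfg)
table.to_tsv(args.out / "trait_table.tsv")
truth.to_json(args.out / "ground_truth.json")
affected = truth.affected.drop(index=table.wildtype)
print(f"trait table: {len(table.strains)} strains x {len(table.traits)} traits "
      f"-> {args.out}/trait_table.tsv")
print(f"planted: {(affected.sum(axis=1) >= 1).mean():.1%} of mutants carry "
      f">=1 effect, {(affected.sum(axis=1) >= 2).mean():.1%} carry >=2")

# a second library with planted phenotype-severity groups (and no copula
# effects) for the cluster-recovery analysis in step 05
grouped_dir = args.out / "grouped"
grouped_dir.mkdir(exist_ok=True)
gcfg = SimulationConfig(effect_fraction=1.0, effect_size_sd=0.0,
                        group_separation_sd=2.0, rng_seed=ints[0])
gtable, gtruth = simulate_trait_table(gcfg)
gtable.to_tsv(grouped_dir / "trait_table.tsv")
gtruth.to_json(grouped_dir / "ground_truth.json")
print(f"grouped library: 4 planted severity groups at "
      f"{gcfg.group_separation_sd:g} SD -> {grouped_dir}")

rng = np.random.default_rng(ints[1])
img_dir = args.out / "images"
img_dir.mkdir(exist_ok=True)
truth_rows = {}
for i in range(args.n_images):
    spec = random_image_spec(rng, noise_sd=3.0)
    img, img_truth = simulate_development_image(spec)
    tifffile.imwrite(img_dir / f"img_{i:03d}.tif", img)
    truth_rows[f"img_{i:03d}"] = {
        "n_interior": sum(not r.touches_edge and r.area >= 200
                          for r in img_truth.records),
        "areas": sorted(r.area for r in img_truth.records
                        if not r.touches_edge and r.area >= 200),
    }
(args.out / "image_truth.json").write_text(json.dumps(truth_rows, indent=1))
print(f"images: {args.n_images} synthetic development fields -> {img_dir}")

expr, expr_labels = simulate_expression_matrix(
    n_genes=len(table.mutants), gene_ids=table.mutants, rng_seed=ints[2])
expr.to_csv(args.out / "expression_matrix.tsv", sep="\t")
expr_labels.rename_axis("gene").to_frame().to_csv(
    args.out / "expression_truth.tsv", sep="\t")
print(f"expression: {expr.shape[0]} gene profiles over {expr.shape[1]} "
      f"timepoints, planted clusters {sorted(set(expr_labels))}")
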