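"""Generate a synthetic soil survey with planted generalist-specialist structure.

The generator draws, per taxon, an environmental tolerance window on each
variable (its true niche breadth is the mean clipped window width), then
fills an occurrence matrix by testing each sample's environment against the
windows and applying imperfect detection. Genomes gain module genes with a
probability that increases (or decreases, for a planted minority) with true
breadth, so every downstream analysis has a known answer to recover.
"""

from nichetraits import synthetic_data as sd

dataset = sd.simulate_dataset(seed=42, n_samples_per_ecosystem=60, n_taxa=120)

print(f"environment: {dataset.env.values.shape[0]} samples x "
      f"{len(dataset.env.variables)} variables in {len(dataset.env.ecosystems)} ecosystems")
print(f"occurrence:  {dataset.occurrence.shape[0]} taxa, "
      f"{int(dataset.occurrence.to_numpy().sum())} presences")
print(f"catalog:     {len(dataset.catalog)} modules across "
      f"{len(set(dataset.strategy_map.values()))} strategies")
print(f"genomes:     {dataset.annotations.counts.shape[1]} KO columns")
print(f"tree:        {len(dataset.tree.leaf_nodes())} tips")

planted = {m: b for m, b in dataset.truth.gene_beta.items() if b}
print(f"planted effect modules: {len(planted)} "
      f"({sum(1 for b in planted.values() if b < 0)} negative)")
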