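# ventbiogeo

Biogeographic province inference for species occurrence data, built around
geographically constrained multivariate regression trees (MRT):

- **community_data** (`ventbiogeo.community`) — delimited site × species
  presence/absence matrices, site coordinate tables, dataset combination,
  and a packaged two-site vent-field fixture (E2/E9).
- **geo_encoding** (`ventbiogeo.encoding`) — alternative longitude
  encodings (`greenwich_pm180`, `east_of_greenwich`, `east_of_60W`) and the
  latitude/longitude constraint table.
- **constrained_mrt** (`ventbiogeo.mrt`) — Hellinger transformation,
  constrained tree growth, weakest-link cost-complexity pruning, v-fold and
  multiple cross-validation, tree-size selection (`most_frequent_min` and
  one-SE rules), province assignment, and a longitude-encoding sensitivity
  scan.
- **raup_crick_clustering** (`ventbiogeo.raupcrick`) — exact hypergeometric
  Raup-Crick similarity (weighted null behind a flag) and average-linkage
  agglomerative clustering with newick export.
- **mol_divergence** (`ventbiogeo.divergence`) — Tamura-Nei (TN93) pairwise
  distances with pairwise deletion, simple indel coding of alignment gaps,
  and rate-based divergence dating with published crustacean rate presets.
- **synthetic_data** (`ventbiogeo.synthetic`) — province-structured
  metacommunity generator (endemicity, detection effort, clustered
  coordinates, optional dateline-straddling province) and TN93 sequence-pair
  simulation.
- **pipeline_cli** (`ventbiogeo.pipeline`, `ventbiogeo.cli`) — end-to-end
  runs with a JSON manifest for exact reproduction.

## CLI

```sh
# simulate a 3-province metacommunity and run the full analysis
ventbiogeo simulate -k 3 --seed 1 --out-prefix scratch/sim
ventbiogeo run --matrix scratch/sim_matrix.tsv --coords scratch/sim_coords.tsv \
    --out scratch/run --replicates 100 --seed 2

# individual stages
ventbiogeo transform matrix.tsv --out hellinger.tsv
ventbiogeo mrt matrix.tsv coords.tsv --scheme east_of_greenwich
ventbiogeo multicv matrix.tsv coords.tsv --replicates 1000
ventbiogeo provinces matrix.tsv coords.tsv --rule one_se
ventbiogeo sensitivity matrix.tsv coords.tsv
ventbiogeo raupcrick matrix.tsv --out-newick dendrogram.nwk
ventbiogeo distance alignment.fasta --preset anomuran_16s
ventbiogeo date 6.45 --rate 0.53
ventbiogeo fixture --out-prefix scratch/esr
```

`ventbiogeo run` writes, per encoding scheme: the cross-validated error
table, the optimal-tree-size frequency table, the selected sizes under both
rules, the province assignment, and the tree (text + JSON); plus the
Raup-Crick similarity matrix, the newick dendrogram, and a `manifest.json`
recording seeds and parameters. Identical config + seeds reproduce the
bundle byte-identically.

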