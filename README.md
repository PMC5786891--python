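# spectraclust

Alignment-free clustering of DNA sequences by genomic signal processing:
each sequence is mapped to four binary indicator channels (Voss
representation, order A, G, C, T), every channel is zero-padded to a common
length and transformed with the DFT, and the squared magnitudes are summed
into one power spectral density (PSD) vector per sequence.  Sets of PSD
vectors are partitioned with a multi-restart K-means under the Euclidean
metric (random initial labels, 50 restarts by default, best objective
kept), and the result is rendered as a radial plot: cluster centroids sit
on evenly spaced rays around the main centroid (the unweighted mean of the
centroids) at their true spectral distance, and member sequences orbit
their centroid at their true distance to it, so radii on the plot are
exact distances.

Also included:

* **decomposition analysis** — how many distinct clusters each annotated
  group (e.g. kingdom) fragments into as k grows;
* **reference comparison** — mean squared distances between each
  discovered cluster's members and centroids built from the true group
  labels (plus a plain centroid-to-centroid distance matrix);
* **synthetic data generator** — labeled sequence families with a
  controlled per-site substitution rate, so the whole pipeline is testable
  without downloads.

## Conventions

The PSD is the full two-sided, unnormalized spectrum of length `n`
(`n = max sequence length` by default, settable with `--psd-length`, e.g.
4100).  Sequences shorter than `n` are zero-padded; longer ones are an
error, never truncated.  The DC bin is kept by default; `--drop-dc` zeroes
it (it encodes only base composition and dominates magnitudes).  IUPAC
ambiguity codes are accepted and contribute zero to every channel; `U` is
read as `T`.  The K-means objective is the total within-cluster sum of
squared Euclidean distances; "best restart" means the minimal final
objective.

## Command line

```bash
# generate a labeled synthetic dataset (FASTA + groups CSV)
spectraclust simulate --spec examples/families_example.yaml --out-dir sim/

# cluster it and write assignments, layout coordinates, and the radial plot
spectraclust cluster --fasta sim/sequences.fasta --groups sim/groups.csv \
    --k 3 --restarts 50 --seed 1 --out-dir run/

# decomposition analysis over several k
spectraclust decompose --fasta sim/sequences.fasta --groups sim/groups.csv \
    --k 2 --k 3 --k 6 --seed 1 --out-dir dec/
```

`cluster` writes `assignments.tsv` (id, cluster `C-1`…, distance to
centroid), `layout_sequences.csv` / `layout_clusters.csv` (radial
coordinates), `radial_plot.png|svg`, `run.log`, and — when a groups file
is given — `msd_matrix.csv` and `centroid_distances.csv`.  All commands
are deterministic for a fixed `--seed`.  A `key=value` config file can be
passed with `--config`; explicit flags override it.

Group files are CSV/TSV with an `id` first column and one column per
taxonomic level; empty cells become the label `Unknown`.

## Library

```python
from spectraclust import (read_fasta, spectrum_set, kmeans_fit, layout, render)

seqs = read_fasta("sim/sequences.fasta")
spectra = spectrum_set(seqs, n="auto")          # m x n PSD matrix
model = kmeans_fit(spectra, k=3, restarts=50, seed=1)
radial = layout(model, spectra)
render(radial, path="plot.png")
```

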