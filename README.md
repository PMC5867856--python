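# adnasex

Ancient-DNA authentication and biological sexing from aligned shotgun
reads: damage profiling and damage-based read selection, the R_Y and R_X
sex statistics with confidence intervals, mitochondrial consensus calling,
and modern-contamination estimation — plus a truth-tagged ancient-read
simulator so the whole pipeline is testable without any sequencing data.

## Who this is for

Analysts working with degraded samples (archaeological, forensic) who have
shotgun or capture reads already mapped to a reference and need to answer:
*is this DNA ancient, what biological sex was the individual, and how much
modern contamination is in the mitochondrial data?*

## The statistics

With `nX`/`nY` unique reads mapped to X/Y and `n_i`, `L_i` the read count
and length of autosome *i*:

* **R_Y** = nY/(nX+nY), 95% CI = R_Y ± 1.96·√(R_Y(1−R_Y)/(nX+nY)).
  Female if the CI upper bound < 0.016; male if the lower bound > 0.075.
* **R_X** = mean over the 22 autosomes of (nX/L_X)/(n_i/L_i),
  95% CI = R_X ± 1.96·SD/√22. Male if the upper bound < 0.60; female if
  the lower bound > 0.80.

Post-mortem deamination is modelled as D(z) = δ·φ^z + ε (C→T from the 5′
end, G→A from the 3′ end), and each read gets a damage score — a
log-likelihood ratio of damage model vs. null — so both statistics can be
recomputed on reads that are unlikely to be modern contaminants
(score ≥ 3). Mitochondrial consensus uses a minimum depth of 5 and a
majority frequency ≥ 80%; contamination is a maximum-likelihood mixture of
the consensus against a panel of candidate modern haplotypes with a
bootstrap CI. Details and design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```python
import adnasex as ax

# a 50,000-read male (XY) shotgun library with untreated damage
cfg = ax.SimConfig(seed=1, karyotype="XY", n_reads=50_000)
ref = ax.simulate_reference(cfg)
reads, truth = ax.simulate_reads(cfg, ref)

kept, stats = ax.filter_reads(reads)          # Q>=30, 36-70 bp
kept = ax.remove_duplicates(kept)
table = ax.count_by_chromosome(kept, ref.lengths)

ry = ax.compute_ry(table.counts["X"], table.counts["Y"])
rx = ax.compute_rx(table)
print(f"R_Y = {ry.estimate:.4f} CI [{ry.ci_low:.4f}, {ry.ci_high:.4f}] -> {ry.call}")
print(f"R_X = {rx.estimate:.4f} CI [{rx.ci_low:.4f}, {rx.ci_high:.4f}] -> {rx.call}")

fit = ax.fit_damage_params(ax.terminal_substitution_profile(kept))
print(f"fitted 5' amplitude delta = {fit.delta:.4f}")
```

prints

```
R_Y = 0.2685 CI [0.2432, 0.2939] -> male
R_X = 0.5227 CI [0.5170, 0.5284] -> male
fitted 5' amplitude delta = 0.2675
```

R_Y sits at the idealized male expectation L_Y/(L_X+L_Y) ≈ 0.277 for the
simulated genome (real hg19 mapping depresses it to ~0.09 through Y
mappability loss — the thresholds account for that), R_X at the male
expectation 0.5 with a CI far below the 0.60 male bound, and the fitted
damage amplitude recovers the configured 0.27 of an untreated library.

The same stages are available from the shell:

```
adnasex simulate --karyotype XY --n-reads 50000 --seed 1 --out sim/
adnasex filter sim/reads.tsv --out filtered.tsv
adnasex sex sim/reads.tsv --lengths sim/lengths.tsv
adnasex mtdna consensus sim/reads.tsv --ref mito.fasta --out consensus.fasta
adnasex run --config run.yaml --out report.json
```

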