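# mscc — methyl-sensitive cut counting methylome analysis

`mscc` implements the full analysis stack for **MSCC** (methyl-sensitive cut
counting), a restriction-enzyme assay that measures CpG methylation at CCGG
sites. Two libraries are built from the same DNA: a **HpaII** library (HpaII
is blocked by CpG methylation, so its tags come from *unmethylated* sites)
and an **inverse** library (HpaII-cut ends are deactivated before MspI, which
cuts regardless of methylation, so its tags come from *methylated* or
hydroxymethylated sites). MmeI releases a fixed 18-bp genomic tag from each
cut, and per-site tag counts from the two libraries quantify methylation.

The package is aimed at method developers and teaching: every stage runs on
synthetic genomes with known ground truth, so estimator bias, normalization,
detection power and false-positive behavior can be measured exactly.

## The model

For a site with true methylation level *p*, sequencing depth *d* and library
efficiencies *e_H*, *e_I*,

    d ~ Poisson(mean_depth)
    m ~ Binomial(d, q),   q = p·e_I / (p·e_I + (1−p)·e_H),   u = d − m

where *u* and *m* are the HpaII- and inverse-library counts. Spike-in
standard DNA passes through each library and calibrates per-library scale
factors *f_L = K / spike(L)* (the constant *K* cancels), giving the estimate

    level = m·f_I / (m·f_I + u·f_H)

Sites with *u + m < 30* raw reads are excluded (the "30+ reads" filter).
Differential methylation uses 200-bp non-overlapping windows and CpG islands
as units (≥ 4 sites quantified in both samples), comparing unweighted unit
means and a pooled-count two-sided Fisher exact test; a unit is a
*consistent* DMR when it exceeds a 25% level change with BH *q* < 0.05 in
every treated-vs-baseline comparison across the timecourse.

## Worked example

```bash
mscc run-all --outdir demo --seed 5
```

simulates a 3×200 kb genome (five samples S0h…S96h under a null timecourse,
mean depth 50), digests it, quantifies methylation, annotates, tests for
DMRs and writes profile tables plus a checksummed `demo/manifest.json`.
From that run:

```text
$ cat demo/stratum_means_cgi_context.tsv
stratum	mean_level	n
cgi	0.03862541041719695	2985
shore	0.18762011158688285	2278
open_sea	0.5430774375350083	9884

$ python -c "import json; print(json.load(open('demo/site_consistency.json')))"
{'eligible': 15090, 'excluded': 71, 'flagged': 1, 'fraction': 6.626905235255136e-05}
```

CpG islands are strongly hypomethylated (~0.04) relative to shores (~0.19)
and open sea (~0.54), and across the five identical-truth samples a single
site out of 15,090 (0.007%, pure sampling noise at depth 50) shows a
consistent >25% methylation change — `demo/dmr.tsv` contains zero
consistent DMRs among its 2,492 eligible windows and CGIs. The
same library API is scriptable directly (`import mscc`), and each stage is
also exposed as its own subcommand (`mscc simulate`, `mscc digest`,
`mscc map`, `mscc quantify`, `mscc annotate`, `mscc diff`, `mscc profile`,
`mscc fixtures`).

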