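# mtartifact

Tools for simulating and diagnosing a false-positive methylation artifact in
mitochondrial bisulfite sequencing.

## The problem

Bisulfite sequencing infers cytosine methylation from conversion chemistry:
unmethylated cytosines deaminate to uracil and are sequenced as T, while
methylated cytosines stay C.  Any cytosine that *escapes* conversion for a
non-biological reason is indistinguishable from a methylated one.  The
mitochondrial genome is a small circular molecule that exists in the cell as
a mixture of topologies — open circles, supercoils, catenanes — and its
compact supercoiled structures can (i) block the bisulfite reagent from
reaching cytosines and (ii) resist sonication shear, so the structured
regions are simultaneously under-released into sequencing libraries and
under-converted.  The visible symptoms are a tight negative correlation
between sequencing depth and apparent methylation, and apparent methylation
that collapses to the chemistry's background failure rate once the genome is
linearised with a single-cutting restriction enzyme (BamHI, G^GATCC, one
site in human mtDNA at position 14,258) before conversion.

`mtartifact` packages this whole story as testable software for people who
analyse (or doubt) mtDNA methylation calls:

* a **generative model** of the artifact — circular mtDNA-like genomes, a
  known true methylome (all-zero by default), a topology-mixed population of
  genome copies in which supercoiled molecules carry *protected windows*,
  and paired-end bisulfite read simulation in which protection raises the
  conversion-failure rate from ε₀ to ε_prot and thins fragment release by a
  factor ρ;
* a **desk-scale read-processing chain** — head trimming, a three-letter
  (C→T / G→A collapsed) seed-and-verify aligner for references up to ~1 Mb
  with a unique-best-hit rule, PCR-duplicate removal, and per-cytosine
  CpG/CHG/CHH methylation calling in the standard cytosine-report format;
* the **diagnostics** — Pearson correlation of log coverage vs log apparent
  methylation over cytosines with apparent methylation > 0; per-region
  min–max summaries ("ND" when uncovered); exact paired sign tests with
  Bonferroni correction for the digested-vs-undigested comparison; NUMT
  length/score correlations; and an exhaustive NUMT contamination screen
  (every possible fixed-length read from methylated and unmethylated NUMT
  copies realigned against mt + nuclear references; the pass condition is
  zero mtDNA-assigned reads).

## Worked example

```python
from mtartifact import ExperimentConfig, run_wmgbs, run_targeted

cfg = ExperimentConfig(seed=1)      # 16,569 bp circular genome, all-zero methylome
shotgun = run_wmgbs(cfg)
c = shotgun.correlation
print(f"r = {c.r:.3f}, p = {c.p_value:.2g}, n = {c.n}")

targeted = run_targeted(cfg)
s_und, s_dig = targeted.summaries["D-Loop"]
st = targeted.sign_tests["D-Loop"]
print(f"D-Loop: undigested {s_und.minimum:.1f}-{s_und.maximum:.1f}% "
      f"vs digested {s_dig.minimum:.1f}-{s_dig.maximum:.1f}%  "
      f"(sign test p_adj = {st.p_adjusted:.2g})")
```

prints (seed 1):

```
r = -0.551, p = 0, n = 6803
D-Loop: undigested 7.0-16.5% vs digested 0.0-2.0%  (sign test p_adj = 4.2e-17)
```

Reading: although the simulated genome carries **no** methylation at all,
the intact (undigested) arm reports up to ~20% apparent methylation in the
protected control region, and apparent methylation is strongly negatively
correlated with depth across ~6,800 cytosines.  Digesting the population
before conversion removes the protection and the signal collapses to the
0.5% background conversion-failure rate — the artifact, reproduced and
diagnosed end to end.

The same machinery is scriptable from a shell:

```bash
mtartifact run-wmgbs --outdir out/wmgbs --seed 1
mtartifact run-targeted --outdir out/targeted --seed 1
mtartifact diagnose --report out/wmgbs/cytosine_report.CX.txt --outdir out/diag
```

`diagnose` and `call` also accept externally produced cytosine reports
(seven-column CX dialect), so real-data per-cytosine tables can be fed
straight into the diagnostics.

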