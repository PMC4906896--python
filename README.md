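# ptxmap

Pseudo-testcross linkage mapping, linkage-disequilibrium and synteny
toolkit for outcrossing species.

Clonally propagated perennials (cranberry, blueberry, grape, raspberry …)
cannot be selfed into inbred mapping panels. The standard workaround is the
**pseudo-testcross**: cross two heterozygous parents and map each parent
separately, because any marker heterozygous in one parent and homozygous in
the other segregates 1:1 among the F1 progeny exactly like a backcross.
`ptxmap` implements that workflow end to end for geneticists building
high-density GBS maps:

* HapMap/CSV genotype parsing, marker-configuration classification
  (ABxAA, AAxAB, ABxAB, ABxCD), missingness/MAF filtering;
* median, principal-component and linear-discriminant (SVD-based)
  imputation of missing calls, with masking cross-validation;
* genome-wide segregation-distortion scans (Pearson χ² with df 1/2/3
  against 1:1, 1:2:1, 1:1:1:1; flag at p < 0.10, exclude at p < 0.001);
* parental bin-map construction — DH recoding, two-point r̂/LOD,
  grouping at LOD > 10 and r̂ < 0.35, cosegregation bins, minimum-spanning-
  tree ordering with ripple refinement, genotyping-error scan, Kosambi
  distances — and integration of the two maps through ABxAB anchors;
* gametic LD (r² = D²/π_A π_a π_B π_b), 5-cM binned decay curves and
  threshold-crossing decay distances;
* Chakravarti method-4 genome coverage, Kb/cM equivalence, Table-style
  per-LG summaries;
* scaffold anchoring, unoriented pseudomolecules, BLAST-hit filtering and
  microsynteny detection (<10 cM / <10 Mbp rule);
* a fully truth-annotated synthetic F1 population generator, so every
  stage is testable without external data.

Key formulas, in the field's notation: Kosambi map distance
`d = 25·ln((1+2r)/(1−2r))` with inverse `r = ½·tanh(2d/100)`; two-point
LOD `(N−R)·log₁₀2(1−r̂) + R·log₁₀2r̂`; gametic LD `D = π_AB − π_A π_B`,
`r² = D²/(π_A π_a π_B π_b)`; Chakravarti method-4 expected LG length
`L·(m+1)/(m−1)`.

See `docs/methods.md` for the model, its assumptions, and every numerical
design decision.

## Worked example

Simulate a reduced cross (3 chromosomes, 450 markers, 150 progeny, 5 %
missing calls, 0.5 % genotyping error) and run the whole pipeline:

```python
from ptxmap.simulate import SimConfig, simulate_cross
from ptxmap.pipeline import run_pipeline

cfg = SimConfig(n_progeny=150, lg_lengths=(100.0, 80.0, 60.0),
                n_markers=450, missing_rate=0.05, error_rate=0.005, seed=7)
gm, truth = simulate_cross(cfg)
res = run_pipeline(gm=gm)
for p, pr in res.parents.items():
    s = pr.summary
    print(f"{p}: {len(s)} LGs, {s['n_markers'].sum()} markers, "
          f"{s['n_bins'].sum()} bins, {s['length'].sum():.1f} cM, "
          f"decay(r2=0.2) = {pr.decay_cm:.1f} cM")
print("integrated markers:", len(res.integrated),
      "| coverage: %.1f%%" % res.coverage.coverage_percent)
```

prints

```
P1: 3 LGs, 161 markers, 86 bins, 210.3 cM, decay(r2=0.2) = 35.0 cM
P2: 3 LGs, 193 markers, 81 bins, 200.3 cM, decay(r2=0.2) = 34.4 cM
integrated markers: 450 | coverage: 98.7%
```

Both parental marker sets resolve into the three simulated chromosomes;
cosegregating markers collapse into bins; the LD decay distance of ~35 cM
is the expected slow decay of a full-sib family at n = 150 (every linked
pair starts in complete disequilibrium, and mean r² falls as (1−2θ)² plus
a 1/n inflation); and coverage just under 100 % reflects the method-4
inflation (m+1)/(m−1) at ~60 markers per chromosome.

The same stages are available from a shell via the `ptxmap` CLI
(`simulate`, `qc`, `impute`, `distort`, `map`, `ld`, `stats`, `anchor`,
`synteny`, `run-all`), each taking `--seed`, `--config` and `--out-dir`
and writing a JSON run manifest. For example:

```sh
ptxmap stats --out-dir out/   # coverage + Kb/cM of the packaged map summary
```

```json
{
  "observed_length_cm": 1112.1,
  "expected_length_cm": 1117.85,
  "coverage_percent": 99.5,
  "kb_per_cm": 422.62,
  "kb_per_cm_int": 422
}
```

The packaged map summary (`ptxmap.stats.load_published_map_summary`)
carries the per-LG lengths and marker counts of the published high-density
cranberry map — 12 linkage groups, 1112.1 cM, 4849 markers — which is the
standard worked input for the coverage and Kb/cM estimators.

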