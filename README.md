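# crcscreen

A colorectal-cancer (CRC) natural-history microsimulator with a
screening-strategy overlay, for comparing noninvasive screening tests —
triennial multitarget stool DNA (mt-sDNA), annual fecal immunochemical
testing (FIT), annual guaiac fecal occult blood testing (FOBT), and
hypothetical triennial blood-based tests at the CMS minimum performance
thresholds (74% CRC sensitivity, 90% specificity) — on life-years gained,
CRC incidence and mortality reductions, and colonoscopy demand.

It is written for health-services and decision modelers who want a small,
fully inspectable cohort model: every person's disease trajectory is an
explicit object, every screening consequence is an event in a life history,
and every comparative number is a paired difference against the same
person's unscreened counterfactual.

## Model

**Natural history** follows the adenoma–carcinoma sequence in continuous
time. For person *i* with standard-normal frailty *Z*ᵢ, adenomas arise from
a non-homogeneous Poisson process with intensity

λᵢ(a) = exp(β₀ + σ·Zᵢ + βₘ·1[male]) · g(a),

where g(a) is a piecewise-constant age effect. Each adenoma grows along
d(t) = d_max − (d_max − d₀)·e^(−λt), with λ solved so the lesion is exactly
10 mm at its drawn "years-to-10 mm" anchor. Malignant transformation has
hazard h(t) = h₁₀ · (d(t)/10)^γ (optionally age- and sex-modified); a
transformed lesion becomes preclinical cancer, advances through AJCC stages
I→IV with exponential dwell times, and presents clinically after a
lognormal sojourn. Post-diagnosis survival is a stage-specific cure
fraction plus an exponential excess hazard with age-band multipliers;
other-cause mortality comes from a sex-specific life table.

**Screening** offers a test on the grid {45, 45+Δ, …, 75}; each offer is
completed with the per-round adherence probability. Test positivity uses
the per-person most-advanced-lesion convention (the way trial sensitivities
are measured): P(+) is the false-positive rate 1−specificity, the
nonadvanced (<10 mm) sensitivity, the advanced (≥10 mm) sensitivity, or the
CRC sensitivity, by the person's most advanced lesion. A positive test
triggers a same-day colonoscopy (always completed) with per-lesion,
size-dependent detection; removal of a not-yet-transformed adenoma
prevents its cancer outright, detection of preclinical cancer diagnoses it
at the current (earlier) stage, findings trigger surveillance colonoscopy,
and a clean follow-up defers rescreening by ten years.

Both arms of every comparison share the person's natural-history
realization (common random numbers), so life-years gained (LYG) per 1000,
incidence/mortality reductions, and resource counts are paired statistics
with small Monte-Carlo error.

The packaged parameter file is a documented **stand-in calibration**
(lifetime adenoma prevalence ≈ 35%, unscreened lifetime CRC risk ≈ 4.5%);
it is not a transcription of any published calibrated model, and every
value can be overridden via a YAML file in the same schema
(`src/crcscreen/data/default_params.yaml`).

## Worked example

```sh
crcscreen simulate mt_sdna --adherence 0.656 --n 20000 --master-seed 1
```

prints

```
mt_sdna @ adherence 0.656: LYG/1000 = 236.8 (SE 14.8), incidence reduction 57.4%, mortality reduction 61.7%
```

meaning: compared with no screening of the same 20 000 simulated people,
triennial mt-sDNA completed with probability 0.656 per offer gains 236.8
life-years per 1000 people over their lifetimes (Monte-Carlo standard
error 14.8), and prevents 57.4% of CRC diagnoses and 61.7% of CRC deaths.
A CSV row with all outcome fields and a JSON metadata sidecar (seed, n,
parameter hash) are written under `results/`.

Other entry points: `crcscreen grid` runs the full strategies × adherence
grid (30–100% plus real-world rates 65.6/42.6/34.4% for
mt-sDNA/FIT/FOBT); `crcscreen threshold` bisects the blood-test adenoma
sensitivity needed to match a stool test's LYG. The same functionality is
available as a library:

```python
from crcscreen import (default_params, load_test_specs, run_strategy,
                       Strategy, AdherenceModel)
params = default_params()
tests = load_test_specs()
s = run_strategy(Strategy(test=tests["blood_s3"]), params, n=20000, master_seed=1)
print(s.lyg_per_1000, s.colonoscopies_per_1000)
```

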