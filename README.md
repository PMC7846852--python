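# rvecv — right-ventricular extracellular volume measurement toolkit

`rvecv` quantifies myocardial **extracellular volume fraction (ECV)** from
paired native / post-contrast T1 maps and hematocrit, with a focus on the
hardest target in cardiac T1 mapping: the **right-ventricular (RV) free
wall**, which is often only one or two pixels thick. It is written for
cardiac-MRI researchers who need a reproducible, scriptable ECV pipeline
and a controlled synthetic test bed for validating thin-wall measurement
strategies.

## The problem and the two samplers

ECV is computed from the contrast-induced change in longitudinal
relaxation rate (ΔR1 = 1/T1_post − 1/T1_pre) of myocardium relative to
blood, scaled by the plasma fraction:

```
ECV = (1 − Hct) · [ (1/T1_myo,post − 1/T1_myo,pre)
                    / (1/T1_blood,post − 1/T1_blood,pre) ]
```

Getting T1_myo for the RV is the hard part. The toolkit implements both
measurement strategies side by side:

* **Planimetric ROI** — a closed polygon contoured inside the wall; pixels
  whose centers fall inside (even-odd rule) are averaged. The
  conventional standard, but error-prone when the wall is 1–2 px thick.
* **Line of interest (LOI)** — an open polyline drawn along the mid-wall;
  the pixels *crossed* by the line (exact supercover: open-square
  intersection, corner touches excluded) are averaged. No contouring of
  the wall borders is needed.

Feasibility rules are enforced per structure: image-quality grade ≤ 2
(sufficient blood/myocardium contrast), maximum wall thickness per ROI
≥ 1 pixel (wall grade ≤ 2, measured on a supersampled mask via a
medial-axis distance transform), and both maps present.

Because no patient images ship with the package, a **synthetic
midventricular short-axis phantom** stands in for them: LV annulus and
blood pool, a thin crescent-shaped RV free wall (0.25–4 px), MOLLI
3(3)3(3)5 inversion-recovery signal simulation with Look-Locker
correction (S(TI) = A − B·e^(−TI/T1*), T1 = T1*(B/A − 1)), subpixel
partial-volume mixing, Gaussian signal noise, and optional inter-frame
misregistration with automatic correction. Ground-truth ECV is planted
analytically, so measured-minus-true error isolates sampling and
partial-volume effects. Agreement between methods is assessed with
Pearson/Spearman correlation and Bland–Altman statistics
(bias ± 1.96·SD limits of agreement, t-based CI of the bias).

## Worked example

Render a synthetic subject with a 1.5-px RV wall, then compute its ECV
table:

```
$ ecv phantom --out demo/subj01 --wall 1.5 --seed 42
phantom written to demo/subj01 (true RV ECV 0.310, wall 1.50 px, grade 2)

$ printf 'subject_id,hematocrit\nsubj01,0.43\n' > demo/hct.csv
$ ecv compute --maps demo --hct demo/hct.csv --out demo/results.csv
wrote 4 rows to results.csv (0 exclusions -> results.exclusions.csv)
```

The results table (abridged):

```
subject_id structure method  t1_myo_pre  t1_myo_post      ecv
    subj01        RV    ROI 1029.117391   607.150000 0.317240
    subj01        RV    LOI 1037.330000   605.043333 0.323548
    subj01        LV    ROI 1018.448544   616.813592 0.300337
    subj01        LV    LOI 1018.659740   617.350649 0.299770
```

Both methods land close to the planted truths (RV 0.310, LV 0.300). The
RV values sit ~0.01 high: at 1.5 px some sampled pixels blend with
adjacent blood, the partial-volume overestimation this package exists to
characterize; the thick LV wall shows no such bias. A cohort-level
comparison of the two methods:

```
$ ecv experiment loi-vs-roi --out demo/compare --seed 1 --subjects 12
n=12 Pearson r=0.981 bias=-0.0041 LoA=[-0.0168, +0.0085]
```

i.e. on 12 synthetic subjects the centerline LOI tracks the planimetric
ROI closely (r = 0.98) with no meaningful systematic offset (limits of
agreement contain zero). `ecv experiment feasibility` sweeps wall
thickness 0.5–3 px and tabulates how ECV error inflates below 1 px.

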