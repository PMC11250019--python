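# fifplan

Semiautomatic **field-in-field (FIF)** forward planning for whole-brain
irradiation (WBI): automatic creation of MLC-blocked sub-beams that
remove 3D dose hotspots, with closed-form beam-weight assignment and a
two-step (2 vs 4 sub-beam) adaptation scheme.

## The problem

WBI is delivered with two parallel-opposed lateral photon fields.  The
head is laterally thinner toward its anterior and posterior poles, so
those regions — the frontal and occipital lobes — receive more than
the prescribed dose.  ICRU guidance asks for the planning target
volume (PTV) to stay within 95–107% of prescription, so planners add
low-weight *sub-beams* whose multileaf collimator (MLC) shadows the
hotspot regions — the FIF technique.  Doing this by hand is slow;
`fifplan` automates it.

## The algorithm

**Step 1.**  Find the hotspot — every PTV voxel with dose strictly
above a threshold D_th (default 105% of prescription) in the original
two-field plan.  Project it through each beam's geometry
(DCS → isocenter frame → gantry/collimator frame → beam's-eye view,
IEC 61217 conventions) into a binary raster in the isocenter plane.
Duplicate each main beam as a sub-beam and advance its MLC leaves, per
leaf row, to fully cover the projected hotspot: a one-sided hotspot is
covered by the leaf on its side; one crossing the field's vertical
centre line is covered from the side with the larger distance d₁/d₂
to the outer hotspot edge.  Then shift weight from each main beam to
its sub-beam in closed form, with D_max the original plan maximum:

    f            = (D_max − D_th) / D_max
    w_main^FIF   = w_main · (1 − f) = w_main · D_th / D_max
    w_sub^FIF    = w_main − w_main^FIF

Dose is linear in beam weights, so unblocked regions keep exactly
their original dose while blocked regions are reduced by f — the
maximum lands on D_th.

**Step 2.**  If Step 1 reduced the PTV's D95 by more than a criterion
(default 1 percentage point), the plan is rebuilt with four sub-beams:
the first pair blocks the region above the intermediate threshold
D_ith = (D_max + D_th)/2, the second pair blocks what still exceeds
D_th in that intermediate plan (main weights reduced once more by
D_th / w_ithmax, the intermediate maximum).  Two shallower blocks
remove the same hotspot at a smaller coverage cost.

Since no clinical planning system is attached, the package includes a
synthetic head phantom (ellipsoid, PTV = body eroded 5 mm, 2.5-mm
grid) and a simplified divergent-beam dose engine
(`exp(−μ_eff·depth)` with inverse square and MLC transmission, exactly
linear in beam weights).  See `docs/methods.md` for models,
parameters, and limitations.

## Worked example

```sh
fifplan generate-phantom --out demo
fifplan autofif --density demo/density.nrrd --ptv demo/ptv.nrrd \
                --plan demo/plan.json --out demo/fif
fifplan report  --dose demo/fif/fif_dose.nrrd --ptv demo/ptv.nrrd --out demo/rep
```

prints

```
phantom written to demo ((61, 81, 69) voxels at 2.5 mm)
scheme: FIF
D_th = 105.0%  criterion = 1.0 pp  D_max(original, PTV) = 106.28%  f = 0.0120
delta D95: step1 = 0.00 pp, final = 0.00 pp
V_105%(PTV): 3.88% -> 0.02%
beam weights:
  main1    main  0.9880
  main2    main  0.9880
  sub1_1   sub1  0.0120
  sub1_2   sub1  0.0120
   d95 = 100.67
    d2 = 104.21
   d98 = 100.43
   d50 = 102.52
 d_max = 105.02
   v95 = 100.00
  v105 = 0.02
    hi = 3.69
```

Reading this: the original opposed-lateral plan put 3.88% of the PTV
above 105% of prescription with a maximum of 106.28%.  Step 1 moved
1.2% of each main beam's weight (f = 0.0120) into a blocking sub-beam;
the hotspot volume fell to 0.02% and the maximum to 105.02%, while the
target coverage was untouched (D95 changed by 0.00 points, V95 stayed
at 100%) — so the two-sub-beam scheme was selected and no escalation
was needed.  The same pipeline is available as library calls
(`fifplan.autofif(plan, density, ptv, FIFConfig())`), and `report.json`
/ `indices.json` / `dvh_ptv.csv` hold the machine-readable outputs.

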