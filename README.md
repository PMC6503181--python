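# stentflow

Virtual coronary intervention (VCI) planning from vessel geometry: deploy
idealized virtual stents in a diseased coronary artery model and predict the
physiological result — the virtual fractional flow reserve (vFFR) — before
and after treatment, without a pressure wire.

**Who it is for.** Researchers in computational hemodynamics who want a
self-contained, testable implementation of the angiography-style VCI
workflow: cross-section vessel models, spline-based virtual stenting,
lumen meshing, steady Navier–Stokes (or a fast reduced-order surrogate)
under a pressure inlet and a generic distal-resistance outlet, and the
serial-lesion ("remove each stenosis in turn") analysis.

## The model in brief

An artery is a sequence of circular cross-sections: center point, lumen
radius `r(s)`, arc length `s` from the proximal inlet. FFR is the
hyperemic pressure ratio

    FFR = P_d / P_a ,   FFR ≤ 0.80 → flow-limiting stenosis

computed here between two marked arc lengths from a steady flow solution
with boundary conditions

    inlet:   P = mean aortic pressure (mmHg → Pa)
    outlet:  P_out = P_venous + Q · R_d ,  R_d = 8.721×10⁹ Pa·s·m⁻³

(`R_d` is a population-average myocardial resistance, used when no
invasive measurement is available). Virtual stenting replaces the stented
segment's trajectory with a least-squares cubic spline and scaffolds the
radii to `max(r, D/2)` with a short edge taper; re-solving gives the
predicted post-treatment vFFR. Two flow backends share one interface:

* `reduced` — per-segment Poiseuille resistance `8μΔs/(πr̄⁴)` plus
  Borda–Carnot expansion losses; closed-form testable, milliseconds.
* `fvm3d` — cell-centered finite-volume SIMPLE solver on a swept
  tetrahedral mesh with boundary inflation layers (prism-agglomerated
  control volumes, implicit resistance-outlet coupling).

See `docs/methods.md` for assumptions, parameters, and numerics.

## Worked example

```bash
# a 50 mm artery, radius 1.5 mm, with a 58% diameter stenosis at mid-vessel
vessel synth --length 50 --radius 1.5 --stenosis 25,20,0.58 --out lad.txt

# baseline physiology (reduced backend)
vessel solve --in lad.txt --backend reduced --out pre.json
# -> vFFR[0.0, 50.0] = 0.9273 (Q = 1.3183e-06 m^3/s)

# deploy a 3.0 x 20 mm virtual stent over the lesion and re-solve
vessel stent --in lad.txt --stent 15,35,3.0 --out lad_stented.txt
vessel solve --in lad_stented.txt --backend reduced --out post.json
# -> vFFR[0.0, 50.0] = 0.9900 (Q = 1.4075e-06 m^3/s)
```

The untreated vessel's vFFR of 0.93 rises to 0.99 after the virtual
stent — the stenosis-free value for this vessel, i.e. the lesion's entire
pressure loss is recovered. The same pipeline runs through the 3D solver
with `--backend fvm3d`, and `vessel mesh` exports the lumen surface/volume
(STL, VTK, VTU) for inspection.

Tandem lesions:

```bash
vessel synth --length 80 --radius 1.5 --stenosis 25,14,0.55 \
    --stenosis 55,14,0.5 --out tandem.txt
vessel tandem --in tandem.txt --lesion 17,33,3.0 --lesion 47,63,3.0 \
    --report strategies.json
# -> baseline vFFR 0.920; best strategy (0, 1) -> 0.984
```

The report ranks every strategy (proximal only, distal only, both) by the
distal vFFR it achieves — the information a wire pullback cannot give,
because each untreated stenosis caps the hyperemic flow seen by the other.

Paired-measurement statistics (`vessel stats --pairs pairs.csv`) compute
Bland–Altman bias and 2·SD limits of agreement, Pearson r with a
through-origin fit, and sensitivity/specificity/PPV/NPV/accuracy at the
0.80 threshold.

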