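# dc3

Joint deconvolution and coupled clustering of scRNA-seq, scATAC-seq and
enhancer–promoter loop (HiChIP) data.

## The problem

Single-cell RNA-seq and ATAC-seq resolve the subpopulations of a
heterogeneous sample, but chromatin-contact assays such as H3K27ac HiChIP
are usually measured in bulk: the loop counts are a mixture over all
subpopulations, and the three assays are run on *different* cells. `dc3`
solves two problems at once — clustering the single-cell modalities so that
cluster identities correspond across assays (*coupled clustering*), and
splitting each bulk enhancer–promoter loop count into per-subpopulation
loop strengths (*deconvolution*). It is aimed at regulatory genomicists who
want subpopulation-specific enhancer–promoter maps and regulatory networks
without sorting cells first.

## The model

With **E** (gene × cell expression), **O** (enhancer × cell accessibility)
and **C** (gene × enhancer bulk loop counts), `dc3` minimizes

```
½‖C − αD⊙(W₁ΛW₂ᵀ)‖²_F + (μ₁/2)‖E − W₁H₁‖²_F + (μ₂/2)‖O − W₂H₂‖²_F
```

subject to non-negativity, simplex columns of H₁/H₂, and Σλₖ = 1. The two
NMF terms cluster each single-cell matrix (W columns = subpopulation
archetypes, H columns = soft assignments); the coupling term models each
loop count as proportional to promoter expression × enhancer openness,
mixed over subpopulations with weights λ. Optimization is by verified
multiplicative updates (monotone by construction) with closed-form α.
Four input combinations are supported (single-cell loop input, or a bulk
RNA/ATAC profile vector replacing one single-cell matrix). Fitted models
yield subpopulation profiles (cluster means, a plug-in loop decomposition
α·d·λₖ·p¹ᵢₖ·p²ⱼₖ, or a Poisson/multinomial MAP allocation), dropout/null
simulation harnesses, and subpopulation-specific TF network analysis with
dense-subnetwork extraction and a degree-preserving permutation test.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import dc3

# simulate a two-cell-type mixture measured by three disjoint-cell assays
E, O, loops, sc_loops, truth = dc3.generate_mixture(
    K=2, m=300, n=500, cells=(146, 746, 200), separation=0.5,
    n_loops=1200, mean_loop_count=10, seed=5)

est = dc3.DC3(n_clusters=2, init="als", random_state=7).fit(E, O, loops)

from dc3.evaluation import clustering_error, matched_profile_pcc
from dc3.deconvolution import cluster_mean_profiles, plugin_loop_profiles

err = clustering_error(truth.labels_rna, est.labels_rna_)
prof = cluster_mean_profiles(E, O, est.labels_rna_, est.labels_atac_, K=2)
P3 = plugin_loop_profiles(prof.P1, prof.P2, est.lambda_, est.alpha_, loops)
pcc, _ = matched_profile_pcc(truth.loop_profile, P3)
print(f"clustering error {err:.3f}, loop deconvolution PCC {pcc.mean():.3f}")
print(f"alpha {est.alpha_:.3f}, lambda {np.round(est.lambda_, 3)}")
```

Output:

```
clustering error 0.000, loop deconvolution PCC 0.998
alpha 0.384, lambda [0.5 0.5]
```

All 146 scRNA cells land in their true subpopulation (error 0.000), and the
plug-in decomposition of the 1200 bulk loop counts correlates at 0.998 with
the true per-subpopulation loop strengths. `alpha` is the fitted coupling
scale (identified only jointly with the scale of the archetypes) and
`lambda` the subpopulation mixing weights (truth: 0.5/0.5).

The same pipeline is scriptable from the shell:

```
dc3 simulate --k 2 --seed 7 --out sim/
dc3 run --expression sim/E.tsv --accessibility sim/O.tsv \
        --loops sim/loops.tsv --k 2 --seed 1 --out model/
dc3 deconvolve --model model/ --method plugin --out profiles/
dc3 evaluate --truth sim/truth.json --model model/ --out report.tsv
```

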