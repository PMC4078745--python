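# dyncausal

Causal structure discovery for dynamic processes, with explicit treatment of
latent processes and of the observation artifacts that corrupt
effective-connectivity analysis of time series (neural signals being the
motivating case: LFP, MEG, fMRI).

## The problem

Granger-causality analysis asks whether the past of process *X* improves the
prediction of process *Y* beyond *Y*'s own past; in its strong form it is a
conditional-independence criterion, measured in nats by the transfer entropy

    T_{X→Y|Z} = I(Y_{i+1}; X^i | Y^i, Z^i)

and accompanied by the instantaneous-causality measure

    T_{X·Y|Z} = I(X_{i+1}; Y_{i+1} | X^i, Y^i, Z^i).

Constraint-based causal discovery (the IC / IC\* family) asks the same kind
of question graphically: which DAGs are compatible with the conditional
independencies in the data, allowing for latent variables.  This package
joins the two.  Its centerpiece, **ICG\***, replaces the variable-level CI
tests of IC\* with process-level Granger and instantaneous-causality tests
and returns a *macroscopic* mixed graph: a directed edge where Granger
causality survives every observed conditioning set, and a bidirectional edge
where instantaneous causality does — which, for autocausal latent processes,
is proof of a latent common driver.  Key signatures (middle process latent):

    X → α → Y   ⟹   T_{X→Y} > 0  and  T_{X·Y} = 0      (latent mediator)
    X ← α → Y   ⟹   T_{X→Y} > 0  and  T_{X·Y} > 0      (latent common driver)

Everything is backed by exact machinery for linear Gaussian VAR(1) models
(`V_{i+1} = C·V_i + ε`): stationary covariances from the discrete Lyapunov
equation, observation maps (mixing, additive noise, subsampling), and
closed-form Gaussian conditional mutual informations — no estimation error
anywhere.  A d-separation engine covering all the graph flavors involved
(DAGs, patterns, embedded patterns, mixed macroscopic graphs) lets you read
the same answers off a hypothesized causal structure instead.

The `experiments` module reproduces the spatial-aggregation study: when each
recorded signal is a weighted sum of finer-scale processes, Granger
causality between the signals is positive in *both* directions even though
every underlying interaction is unidirectional, and the inconsistent reverse
measure r = T_{Y→X}/T_{X→Y} routinely reaches order 1.

## Worked example

A latent common driver versus a latent mediator, from the library:

```python
import numpy as np
from dyncausal import VARModel, ObservationMap, transfer_entropy, instantaneous_causality
from dyncausal.inference import GaussianGrangerOracle, icg_star

# latent common driver: a -> X, a -> Y; only X and Y observed
C = np.array([[0.5, 0.5, 0.0],
              [0.0, 0.5, 0.0],
              [0.0, 0.5, 0.5]])
model = VARModel(C, names=("X", "a", "Y"))
obs = ObservationMap.selecting(model, ("X", "Y"))

print(transfer_entropy(model, obs, "X", "Y").value)        # 0.004790510295903161
print(instantaneous_causality(model, obs, "X", "Y").value) # 0.02686385903245192
print(icg_star(GaussianGrangerOracle(model, obs), ["X", "Y"]))
```

Both measures are positive and no conditioning set can cancel the
instantaneous one, so ICG\* prints a single bidirectional edge —
`MixedMacroGraph(..., bidirectional=frozenset({frozenset({'X', 'Y'})}), ...)`
— correctly reporting "at least one latent common driver" rather than the
spurious X→Y and Y→X arrows a naive pairwise Granger analysis would draw.
Re-routing the same coupling strength through a mediator (`X → a → Y`)
instead gives `T_{X→Y} = 0.0483`, `T_{X·Y} = 0.0` and the single directed
edge X→Y.

The same inference runs from the command line against ground-truth graphs or
model configs:

```sh
dyncausal fixtures --name common_driver_pair --out common_driver.json
dyncausal icgstar --graph common_driver.json          # → one bidirectional edge
dyncausal experiment rmap --out-dir results/  # the aggregation r-map + metadata
```

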