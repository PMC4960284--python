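# gonogonet

Connectionist simulation of **equivalence-class formation under the go/no-go
procedure with compound stimuli**.

In behavior-analytic research on stimulus equivalence, participants trained
on conditional relations (A1–B1, B1–C1, …) often come to respond correctly
to *untrained* relations such as A1–C1 — evidence that the stimuli have
merged into an equivalence class. The go/no-go procedure with compound
stimuli probes this without assigning sample/comparison roles: a trial
presents an unordered pair of stimuli, a *go* response is reinforced for
same-class compounds and withheld (*no-go*) for mixed-class compounds.

`gonogonet` simulates this preparation with a small feedforward neural
network, for researchers in computational behavior analysis who want a
RELNET-free model of emergent relations:

* each input unit stands for one stimulus; a compound {S₁, S₂} is the binary
  vector with 1 at the two member positions (so a relation and its symmetric
  counterpart share one vector — transitivity can be tested, symmetry cannot);
* a single logistic-sigmoid output unit represents the response, target 1
  (*go*) or 0 (*no-go*);
* training is online backpropagation on the squared error, with weight
  update Δw(t) = −η ∇E + α Δw(t−1), defaults η = 0.3 and α = 0,
  weights initialized uniformly on [0, 1);
* training stops when the error readout over the whole trial table falls to
  0.0025 (mean squared error by default; a strict root-mean-square variant
  is available);
* testing runs with frozen weights; an output activation ≥ 0.85 counts as
  *go*, ≤ 0.15 as *no-go*, anything between as inconsistent responding.

Two experiments are built in. **exp1** trains 11 compounds over nine stimuli
— the AB/BC baseline of two three-member classes plus an auxiliary class
(X, Y, Z) emulating a participant's pre-experimental history. **exp2** drops
the auxiliary class (8 compounds over six stimuli). Both then test the four
AC transitivity compounds. Each *run* of an experiment is an independent
simulated participant with its own random initial weights.

## Worked example

```python
from gonogonet import EquivalenceExperiment

model = EquivalenceExperiment.experiment1()   # auxiliary-class condition
results = model.fit(n_runs=6, base_seed=1)    # six simulated participants
print(results.summary())
```

```
Go/no-go equivalence simulation — exp1
  runs: 6  (base_seed=1)
  trials/epoch: 11, hidden units: 3, lr: 0.3, momentum: 0.0, stop: mse <= 0.0025

 run  converged  epochs  iterations  act_A1C1   label_A1C1  act_A1C2   label_A1C2  act_A2C2 label_A2C2  act_A2C1   label_A2C1  class_formed  inverse_pattern
   0       True    1053       11583     0.584 inconsistent     0.187 inconsistent     0.945         go     0.199 inconsistent         False            False
   1       True    1402       15422     0.946           go     0.118        no_go     0.973         go     0.117        no_go          True            False
   2       True     948       10428     0.963           go     0.129        no_go     0.947         go     0.139        no_go          True            False
   3       True    1222       13442     0.938           go     0.090        no_go     0.960         go     0.094        no_go          True            False
   4       True    1249       13739     0.959           go     0.147        no_go     0.958         go     0.146        no_go          True            False
   5       True    1371       15081     0.483 inconsistent     0.921           go     0.085      no_go     0.921           go         False            False

  mean epochs to criterion     : 1207.5
  mean iterations to criterion : 13282.5
  runs forming classes         : 4/6
  runs with inverse pattern    : 0/6
  non-convergent runs          : 0/6
```

Each row is one simulated participant: how many epochs (passes over the
11-trial table) it needed to reach the stopping criterion, its four frozen
test activations, and whether all four fell in their expected bands
(`class_formed`). Here four of six runs form the classes A1B1C1 and A2B2C2;
runs 0 and 5 fail the transitivity test, run 5 with a partially *inverted*
response pattern. Removing the auxiliary class
(`EquivalenceExperiment.experiment2()`) slows training and largely abolishes
class formation, with fully inverse patterns appearing instead.

The same is available from the shell:

```
gonogonet run --experiment exp1 --runs 6 --seed 1 --out-dir results
gonogonet replicate --runs 6 --seed 1        # both conditions side by side
gonogonet tables --experiment exp1           # the encoded trial table as CSV
gonogonet gradcheck                          # finite-difference gradient audit
```

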