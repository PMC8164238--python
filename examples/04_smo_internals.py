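"""A look inside the SMO optimizer on an analytically solvable problem.

The 1-D two-point problem x = (+1, -1), y = (+1, -1) has the closed-form
dual maximizer lambda = (1/2, 1/2), giving w = 1 and b = 0 with margin
points at +-1.  Debug mode records the dual objective after every accepted
two-multiplier step, certifying monotone ascent.
"""

import numpy as np

import acpsmo as a

prob = a.TrainingProblem(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), C=10.0)
model = a.train_smo(prob, debug=True)
print(f"lambda = {model.lambdas}, w = {model.w}, b = {model.bias}")
print(f"dual objective = {model.dual_objective}  (closed form: 0.5)")
print(f"f(0) = {a.decision_value(model, np.array([0.0]))}  (the midpoint is on the boundary)")
print(f"f(+1) = {a.decision_value(model, np.array([1.0]))}, "
      f"f(-1) = {a.decision_value(model, np.array([-1.0]))}  (margin points at +-1)")

# a harder problem: 1-D XOR-like labels need the rbf kernel
X = np.array([[-3.0], [-1.0], [1.0], [3.0]])
y = np.array([1.0, -1.0, -1.0, 1.0])
trainer = a.SmoTrainer(a.TrainingProblem(X, y, C=10.0, kernel=a.KernelSpec("rbf", gamma=1.0)),
                       debug=True)
trainer.solve()
print(f"rbf XOR-like: {len(np.flatnonzero(trainer.alphas > 0))} support vectors of 4, "
      f"KKT violation = {trainer.kkt_violation():.2e}")
print("dual objective trace (monotone):",
      " -> ".join(f"{v:.4f}" for v in trainer.objective_trace[:6]),
      "..." if len(trainer.objective_trace) > 6 else "")
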