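# Default hyperparameter grids for the comparison study, one block per base
# algorithm.  Option spellings that newer library versions renamed
# ('auto' max_features, GBT loss 'deviance', SGD loss 'log') are translated
# at estimator-construction time so this file can stay as declared.
DT:
  criterion: [gini, entropy]
  splitter: [best, random]
  max_features: [auto, sqrt, log2, null]
KNN:
  n_neighbors: [15, 31]
  weights: [uniform, distance]
  algorithm: [ball_tree, kd_tree]
NC:
  shrink_threshold: [0.01, 0.1, 0.2, 0.3]
GNB:
  var_smoothing: [1.0e-7, 1.0e-8, 1.0e-9, 1.0e-10, 1.0e-11, 1.0e-12]
MNB:
  alpha: [0, 0.1, 0.5, 0.8, 1]
CNB:
  alpha: [0, 0.1, 0.5, 0.8, 1]
BNB:
  alpha: [0, 0.1, 0.5, 0.8, 1]
MLR:
  solver: [newton-cg, lbfgs, saga, sag]
RRC:
  alpha: [1.0e-3, 1.0e-2, 1.0e-1, 1]
  solver: [svd, cholesky, lsqr, sparse_cg, sag, saga]
LCSGD:
  loss: [hinge, log, modified_huber, squared_hinge, perceptron]
  alpha: [1.0e-3, 1.0e-2, 1.0e-1, 1]
  learning_rate: [constant, optimal, invscaling, adaptive]
  eta0: [0.01, 0.001, 0.0001]
PAC:
  C: [0.001, 0.01, 0.1, 1]
  loss: [hinge, squared_hinge]
SVC:
  loss: [hinge, squared_hinge]
  C: [0.001, 0.01, 0.1, 1]
RF:
  n_estimators: [300, 500, 800]
  criterion: [gini, entropy]
  bootstrap: [true, false]
  max_features: [auto, sqrt, log2, null]
ERT:
  n_estimators: [300, 500, 800]
  criterion: [gini, entropy]
  bootstrap: [true, false]
  max_features: [auto, sqrt, log2, null]
GBT:
  loss: [deviance, exponential]
  learning_rate: [0.1, 0.01, 0.001]
  subsample: [0.1, 0.5, 0.9]
  n_estimators: [300, 500, 800]
  max_features: [auto, sqrt, log2, null]
EGBT:
  tree_method: [auto, exact, approx, hist]
  grow_policy: [depthwise, lossguide]
  n_estimators: [300, 500, 800]
  learning_rate: [0.001, 0.01]
  max_depth: [10, 15, 20, 50, 100]
paper_gbt:
  learning_rate: [0.1, 0.01, 0.001]
  subsample: [0.1, 0.5, 0.9]
  n_estimators: [300, 500, 800]
  max_features: [auto, sqrt, log2, null]
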