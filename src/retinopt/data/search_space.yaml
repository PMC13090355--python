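# Hyperparameter search space for tuning the fundus classifier:
# augmentation settings plus transfer-learning configuration.
- {name: rotation, kind: continuous, lower: 0.0, upper: 30.0}
- {name: width_shift, kind: continuous, lower: 0.0, upper: 0.2}
- {name: height_shift, kind: continuous, lower: 0.0, upper: 0.2}
- {name: zoom, kind: continuous, lower: 0.0, upper: 0.2}
- {name: shear, kind: continuous, lower: 0.0, upper: 0.2}
- {name: h_flip, kind: boolean}
- {name: v_flip, kind: boolean}
- {name: optimizer, kind: categorical, choices: [Adam, SGD, RMSprop]}
- {name: batch_size, kind: categorical, choices: [16, 32, 64]}
- {name: tl_learn_ratio, kind: continuous, lower: 0.0, upper: 30.0}
- {name: learning_rate, kind: continuous, lower: 0.0001, upper: 0.01}
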