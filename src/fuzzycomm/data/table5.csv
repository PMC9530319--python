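subject_id,auditory,visual,memory,comprehension,judgment,expression,attention,speech_energy,speech_speed,label
1,61.41,87.65,29.16,77.79,89.99,54.36,63.99,63.82,54.81,3
2,98.79,92.60,64.59,88.87,98.35,86.21,86.23,61.13,38.32,2
3,68.15,75.91,40.02,83.42,88.89,69.02,67.01,56.00,39.55,2
4,96.31,93.71,76.45,98.91,98.62,94.34,91.32,67.22,40.62,1
5,96.75,94.62,64.59,97.58,78.92,74.52,88.95,74.22,55.86,1
6,23.76,66.69,11.52,6.68,36.68,16.55,27.20,65.31,13.45,4
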