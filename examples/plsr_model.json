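{
 "schema": "nirscreen.plsr_model/1",
 "x_mean": [
  -0.6852498013858148,
  -0.034093271529980686,
  -0.0297211418882465,
  0.2925105240769618
 ],
 "y_mean": 99.33289884363455,
 "weights": [
  [
   0.7027010040491104,
   0.2832008878204041
  ],
  [
   0.5230122981744839,
   0.3803366308209047
  ],
  [
   0.35432411756256454,
   -0.814666560460593
  ],
  [
   0.32729780717280543,
   -0.3338558066903202
  ]
 ],
 "loadings": [
  [
   0.6201718627033935,
   0.05990863916138851
  ],
  [
   0.4121762912482703,
   0.6452926875528033
  ],
  [
   0.5917306180694359,
   -0.7731078378564323
  ],
  [
   0.4245885793574843,
   -0.32283479344282395
  ]
 ],
 "y_loadings": [
  0.7503727426493912,
  0.5048930711647963
 ],
 "coefficients": [
  0.7736648373673854,
  0.6614362315749138,
  -0.09331132693306579,
  0.12519040376163854
 ],
 "a": 2,
 "grid": [
  740.0,
  741.0,
  742.0,
  743.0
 ]
}
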