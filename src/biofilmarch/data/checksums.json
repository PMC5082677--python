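{
  "table2.csv": "af69e29fe359248a031b344984b13b2e311425a6b955330092cca42806aa0910",
  "table3.csv": "79ebafe4778f5ed957401cea67ce4fcd8041be0825ce3375a4d7884a2ce7b2a2",
  "table4.csv": "8321da71274c8e7e32f0a320757f4c651265de083f3bebf8fb2523f4760111a1",
  "table5.csv": "bd3f5489e0e830fb71ab486182db19777c6039a9bae69dbedad3584cb5c46be6"
}
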