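{
 "version": 1,
 "K": 100,
 "mean_vector": [
  0.08887216991598115,
  0.13328783292398752,
  0.16659378966562516,
  0.1940001751714728,
  0.21823231847378308,
  0.24008664456975037,
  0.26003019150456785,
  0.2786118317787498,
  0.29604265762950244,
  0.3124821333179256,
  0.32814183639425026,
  0.34309233081045737,
  0.3573822265825629,
  0.3711145700160349,
  0.38435706818976995,
  0.3972241370426501,
  0.4096519839111258,
  0.42169750683684115,
  0.43338541171047107,
  0.44479657242333265,
  0.4558755583639544,
  0.4667394218171203,
  0.47734427470459684,
  0.4877428400356743,
  0.4979124967709496,
  0.5078855176562777,
  0.5176707829513836,
  0.5272668872825297,
  0.5366828637179097,
  0.5459161570236912,
  0.5550096532430375,
  0.5640189948945683,
  0.5728311174573822,
  0.581493793031289,
  0.590089902080132,
  0.5985225534431592,
  0.6068093052513749,
  0.6150370099057666,
  0.623134479653561,
  0.6311397943975935,
  0.6390001701911536,
  0.6467876323303363,
  0.6544965458633841,
  0.6620865217026681,
  0.6696290375145838,
  0.6770726955272102,
  0.6844307825707103,
  0.6917409853988088,
  0.6989204136878301,
  0.7060403993835823,
  0.7131138234563756,
  0.720101991246796,
  0.7270402067964671,
  0.7338856662454364,
  0.7406686309504958,
  0.747426667324273,
  0.7540803053422244,
  0.7607254695944611,
  0.767306466748067,
  0.7738305973592852,
  0.7803011566316492,
  0.786679102755442,
  0.7930179430903423,
  0.7993111525890751,
  0.8055656001274881,
  0.8117852002592532,
  0.8179619904195757,
  0.8240464636841208,
  0.8301240585275833,
  0.8361838731853127,
  0.8421354218398813,
  0.8480584578206445,
  0.8539654535992666,
  0.859806273134326,
  0.8656019018676109,
  0.8714025512762684,
  0.8771400697247016,
  0.8828374183532272,
  0.8884894436590681,
  0.8941120613896146,
  0.8997163467729898,
  0.9052394424005686,
  0.9107874045081495,
  0.9162988637419939,
  0.921744421503228,
  0.9271738558977406,
  0.9325746044163155,
  0.9379286214091755,
  0.9432382975564026,
  0.948554672521936,
  0.9538454769632109,
  0.9590734705262108,
  0.9642897485559616,
  0.9694508187350315,
  0.9746384771512652,
  0.9797685385391933,
  0.9848699857707747,
  0.9899284567482199,
  0.9949737289996367,
  1.0
 ],
 "loadings": [
  [
   0.04288417589104254,
   0.06232122153592223,
   0.07635954210342377,
   0.08695835429146809,
   0.09602306251911844,
   0.10357524930567974,
   0.10967686141100476,
   0.11539053074722576,
   0.12029054040045228,
   0.12407651000648491,
   0.1278455333562131,
   0.1309014170824818,
   0.13382411607825426,
   0.13600840839053588,
   0.13829004677467321,
   0.14009669649831746,
   0.14148555563814727,
   0.14280202030100866,
   0.14360173952441746,
   0.14428502118953598,
   0.1446627878356002,
   0.14493246777290458,
   0.14524342400393186,
   0.14520725533835824,
   0.14509551442902857,
   0.14462972837531415,
   0.14429004122641584,
   0.14357832120362038,
   0.1428704252288803,
   0.1418713475977069,
   0.14072776802769899,
   0.1397783722614417,
   0.13845001944112312,
   0.13719004287128442,
   0.135905143148117,
   0.13444444419454982,
   0.13306264858666692,
   0.13136349969281388,
   0.12978545145597567,
   0.1281352357778522,
   0.12633080216625717,
   0.1246385290601077,
   0.1228214834027087,
   0.12085987492047316,
   0.1189571650358844,
   0.11710322160877135,
   0.11506541158148242,
   0.11302186906036032,
   0.11099747263520308,
   0.10898614400426258,
   0.10675696074029821,
   0.10455816222896246,
   0.10243504732758565,
   0.10030005165351698,
   0.09804824309942275,
   0.09572897794902933,
   0.09349316187966353,
   0.09122700726957404,
   0.08894176677643059,
   0.0866442418149905,
   0.08424074029613739,
   0.0821041452372716,
   0.07974525722811657,
   0.0775150670929526,
   0.07524948795682647,
   0.07290964754257788,
   0.07044014439419255,
   0.0682160255912267,
   0.06579069929432474,
   0.06345965389590233,
   0.0611165073786103,
   0.05885030313040907,
   0.056594402235160095,
   0.054434991115441964,
   0.05221006768126676,
   0.04990218471345305,
   0.047671865392848255,
   0.04548820955629449,
   0.043274619305092486,
   0.04093261146418898,
   0.03881210029134616,
   0.03675105998316062,
   0.03462907466583446,
   0.032389469222945104,
   0.030317744698786363,
   0.0281660576087111,
   0.0260588351922107,
   0.023984222736695232,
   0.021985853070013415,
   0.019914137269548333,
   0.017813828070940715,
   0.01581051149730812,
   0.013776135883538754,
   0.011708509919932528,
   0.009716018591061245,
   0.007666215549107903,
   0.005682460810815517,
   0.0038186116141476776,
   0.0018701394486028266,
   -0.0
  ],
  [
   0.09648744843506202,
   0.13758748712124602,
   0.16113913584888623,
   0.17622194524359658,
   0.18545173834583303,
   0.19063432807251351,
   0.19254195740675986,
   0.19119849432154004,
   0.18870455957907492,
   0.1840012942300209,
   0.17767707430708274,
   0.17086441340129405,
   0.16379027816785063,
   0.15546309930028404,
   0.1466232044853484,
   0.1371256065742187,
   0.12726615093914592,
   0.11755498823446843,
   0.10758100985690261,
   0.09728023928638808,
   0.08695795382938688,
   0.07669094263846575,
   0.06642964319422073,
   0.05641367460064278,
   0.04655161638675575,
   0.03686902266119669,
   0.027684500758506297,
   0.018497798249689425,
   0.009328621058973304,
   0.000507726429253643,
   -0.007994555621406009,
   -0.016234352876332698,
   -0.024040204923098097,
   -0.03172918943171363,
   -0.03912644443137645,
   -0.04610823662880643,
   -0.0525846553828283,
   -0.0590573620578395,
   -0.06453012654392057,
   -0.06984020867412234,
   -0.07499847395776606,
   -0.07988891562781082,
   -0.08444906333499155,
   -0.08874559175328858,
   -0.09284095872309124,
   -0.09649035264085704,
   -0.10014011650555017,
   -0.10325881738023177,
   -0.1059845610177057,
   -0.10839792746782638,
   -0.11016841751436231,
   -0.11205938279295706,
   -0.11345174110481736,
   -0.11454757631857575,
   -0.11551551041356045,
   -0.11610093794516822,
   -0.11668992236763229,
   -0.11677698830739407,
   -0.11682328428807102,
   -0.11647605925101814,
   -0.11590457022277946,
   -0.11511894437119367,
   -0.11414825627917043,
   -0.1129735464011476,
   -0.11161749753094367,
   -0.1101363916981526,
   -0.10818098620784503,
   -0.10618203306690482,
   -0.10394201982317818,
   -0.10164826305903728,
   -0.09916847042228855,
   -0.09653163882723098,
   -0.09394360272179456,
   -0.09145312188980094,
   -0.08855019893776285,
   -0.08555675313035122,
   -0.08214215774961758,
   -0.07921288103053255,
   -0.07633396549979447,
   -0.07286126364357232,
   -0.06937422363885101,
   -0.06612189147495497,
   -0.06271222948808822,
   -0.05914493494412017,
   -0.05560071011238917,
   -0.05186797759772792,
   -0.04830477617325072,
   -0.04472135648875126,
   -0.04107066137401463,
   -0.0374543511768314,
   -0.03346555898759997,
   -0.029681886638133117,
   -0.02580629491344278,
   -0.02234409904382613,
   -0.018564897808380613,
   -0.01470311596313611,
   -0.01109308417857517,
   -0.0072193740623899974,
   -0.0033860795581140226,
   0.0
  ]
 ],
 "eigenvalues": [
  0.06803036526926663,
  0.020144351902207498
 ],
 "total_variance": 0.12288335256405009,
 "training_params": {
  "intensity": 100000.0,
  "n_points": 99813,
  "n_after_edge_filter": 92872,
  "seed": 190346071
 }
}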