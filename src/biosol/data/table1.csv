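name,smiles,set,mw,logd65,psa,rotb,logs_phb,logs_fassif,logs_hif,tm_c
Albendazole,,Te,265.3,3.2,79.7,6,-5.49,-5.14,-4.45,178.1
Amiodarone,,Tr,645.3,5.2,193.0,9,-7.3,-3.26,-3.23,159.0
Amitriptyline,,Tr,277.4,2.4,2.2,3,-2.49,-2.5,,196.5
Amprenavir,,Tr,505.6,1.7,138.0,13,-3.47,-3.65,-3.74,72.0
Aprepitant,,Te,534.4,4.4,325.0,8,-6.16,-4.37,-4.61,252.0
Astemizole,,Tr,458.6,4.4,57.6,8,-4.38,-3.67,-4.68,174.4
Atovaquone,,Tr,366.9,3.7,155.0,2,-5.93,-5.29,-6.06,224.0
Azelnidipine,,Te,582.7,6.0,174.0,8,,-3.97,,122.0
Bicalutamide,,Tr,430.4,2.6,251.0,7,,-4.65,,273.0
Bromazepam,,Tr,316.2,1.8,144.0,0,,-3.42,,243.0
Bromocriptine,,Tr,654.6,3.6,167.0,6,,-4.05,,215.0
Carbamazepine,,Tr,236.3,2.6,73.5,1,-3.27,-3.0,-2.92,191.0
Carvedilol,,Te,406.5,2.4,70.9,10,-3.95,-3.86,-4.05,114.1
Celecoxib,,Tr,381.4,3.5,222.0,2,,-4.29,,158.0
Cilostazole,,Te,369.5,2.8,139.0,7,,-4.77,-4.76,159.0
Cinnarizine,,Tr,368.5,4.3,2.6,5,-5.42,-4.44,-4.28,119.0
Cisapride,,Tr,466.0,2.6,182.0,9,-5.27,-4.86,,110.0
Clotrimazole,,Tr,344.9,5.2,50.4,4,-5.17,-5.0,-4.13,142.0
Cyclosporine,,Te,1202.6,3.0,179.0,15,-5.8,-5.32,-5.54,150.0
Danazol,,Tr,337.5,3.6,68.8,1,-5.75,-4.6,-4.84,227.0
Diazepam,,Te,284.8,2.9,105.0,0,-3.91,-3.64,-3.28,131.6
Diclofenac,,Tr,296.2,2.2,169.0,4,-2.78,-2.59,-2.52,158.0
Diethylstilbestrol,,Tr,268.4,4.8,80.2,2,-4.31,-3.83,-3.85,171.0
Digoxin,,Te,781.0,1.4,241.0,7,-4.69,-4.66,,249.0
Dipyridamole,,Te,504.6,1.8,103.0,12,-4.9,-4.64,-4.24,163.0
Disopyramide,,Te,339.5,-0.2,58.7,8,-3.24,-3.03,,96.4
Efavirenz,,Te,315.7,3.9,214.0,3,,-3.41,,139.0
Felodipine,,Tr,384.3,4.8,136.0,4,-5.51,-3.85,-4.44,143.0
Fenofibrate,,Te,360.8,5.3,138.0,5,-6.26,-4.58,-4.26,79.0
Flufenamic acid,,Tr,281.2,2.6,167.0,3,-2.75,-2.48,-2.82,133.5
Fluoxetine,,Tr,309.3,1.6,109.0,7,,-2.35,,132.8
Gefitinib,,Te,446.9,3.8,147.0,8,-5.04,-3.72,-3.72,119.0
Glibenclamide,,Tr,494.0,3.9,203.0,10,-5.04,-5.02,-4.12,173.6
Griseofulvin,,Tr,352.8,2.5,135.0,3,-4.38,-4.18,-4.32,219.0
Halofantrine,,Te,500.4,6.0,252.0,11,,-4.07,,77.0
Haloperidol,,Tr,375.9,2.0,160.0,5,-3.68,-3.53,,151.0
Ibuprofen,,Tr,206.3,1.8,73.8,4,,-2.17,-2.02,76.0
Indinavir,,Tr,613.8,3.0,72.5,14,-3.9,-4.31,-4.16,167.5
Indomethacin,,Te,357.8,1.5,185.0,3,-3.21,-2.91,-2.46,159.8
Indoprofen,,Te,281.3,0.7,102.0,3,-2.98,-2.66,,211.4
Irbesartan,,Tr,428.5,4.0,108.0,5,-3.62,-3.58,-3.54,180.5
Isotretinoin,,Te,300.4,4.4,74.7,0,,-3.76,,174.0
Ivermectin,,Te,875.1,4.7,112.0,8,-6.1,-3.86,,150.0
Ketoconazole,,Tr,531.4,3.9,181.0,8,-4.56,-3.5,-3.98,146.0
Lansoprazole,,Tr,369.4,1.8,161.0,6,-4.17,-3.97,,178.0
Loperamide,,Tr,477.1,3.9,112.0,8,-4.04,-3.67,,130.0
Lopinavir,,Te,628.8,4.2,67.0,17,-5.76,-4.04,-4.67,124.0
Lorazepam,,Tr,321.2,2.6,213.0,0,-3.44,-2.93,,167.0
Loviride,,Tr,351.2,3.2,177.0,4,-5.55,-4.92,-3.71,286.8
Naproxen,,Tr,230.3,1.3,84.5,3,-3.0,-2.67,-2.05,155.6
Nefazodone,,Tr,470.0,3.9,110.0,10,,-3.27,,83.5
Nelfinavir,,Te,567.8,4.7,83.8,11,-6.16,-3.68,-4.01,349.8
Nevirapine,,Tr,266.3,1.7,55.9,1,-3.51,-3.14,,196.1
Nimesulide,,Tr,308.3,2.3,164.0,4,-4.13,-3.93,-3.56,144.0
Nitrendipine,,Tr,360.4,3.5,126.0,4,-4.95,-4.35,-4.95,157.7
Omeprazole,,Tr,345.4,1.9,76.9,5,-3.28,-3.1,-3.03,156.0
Panadiplon,,Tr,335.4,2.5,57.5,2,-3.64,-3.6,,169.0
Phenazopyridine,,Tr,213.2,2.8,115.0,0,-3.08,-2.67,,139.0
Phenytoin,,Tr,252.3,2.2,113.0,2,,-3.81,-3.77,295.6
Pranlukast,,Tr,481.5,3.3,177.0,8,-5.17,-3.75,,236.0
Praziquantel,,Te,312.4,2.2,55.0,2,-3.17,-3.08,,139.0
Probenecid,,Te,285.4,0.0,132.0,6,-2.34,-2.24,-2.59,198.9
Probucol,,Te,516.9,10.0,14.9,8,-8.94,-5.18,-5.75,126.0
Progesterone,,Tr,314.5,3.8,63.1,1,-4.45,-4.09,-4.08,128.0
Quinidine,,Tr,324.4,1.5,39.4,4,-2.19,-2.16,-2.7,174.0
Rifampicin,,Te,823.0,3.0,158.0,4,-2.92,-2.61,-2.14,183.0
Riluzole,,Tr,234.2,2.3,159.0,2,,-2.58,,119.0
Rimonabant,,Tr,463.8,5.3,227.0,2,-6.39,-4.62,-4.93,154.7
Ritonavir,,Tr,721.0,4.6,77.9,22,-5.27,-5.07,-4.32,120.0
Rofecoxib,,Tr,314.4,2.7,119.0,1,-4.61,-4.53,,207.0
Salsalate,,Tr,258.2,0.8,119.0,2,,-2.21,,147.0
Saquinavir,,Te,670.9,4.1,152.0,15,-3.93,-3.57,-4.24,349.8
Sertraline,,Tr,306.2,2.8,135.0,2,,-3.1,,219.0
Spironolactone,,Te,416.6,3.0,111.0,2,,-4.21,,134.5
Sulfasalazine,,Tr,398.4,0.3,188.0,5,-3.49,-3.34,-2.86,255.0
Tamoxifen,,Tr,371.5,4.8,8.6,5,-4.8,-3.38,-3.77,97.8
Tamsulosin,,Te,408.5,1.1,121.0,11,,-2.45,,226.0
Telmisartan,,Tr,514.6,4.5,79.8,4,,-5.37,,269.0
Terfenadine,,Tr,471.7,3.5,46.2,9,-4.62,-3.74,,149.6
Tipranavir,,Tr,602.7,6.0,189.0,12,-5.19,-4.47,-4.0,86.0
Tolectin,,Te,257.3,0.1,99.5,2,,-2.14,,156.0
Tolfenamic acid,,Tr,261.7,2.9,129.0,2,-3.98,-3.62,,213.0
Troglitazone,,Te,441.6,4.9,143.0,5,,-4.96,,184.0
Warfarin,,Tr,308.3,3.1,70.8,4,-3.19,-2.94,-2.99,161.0
Voriconazole,,Tr,349.3,2.1,146.0,5,,-2.72,,127.0
Zafirlukast,,Te,575.7,4.1,123.0,10,,-5.44,,139.0
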