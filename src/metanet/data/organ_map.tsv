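raw_tissue	canonical_organ
Bladder Urothelial Carcinoma	bladder
Breast Invasive Ductal Carcinoma	breast
Breast Invasive Lobular Carcinoma	breast
Breast Cancer	breast
Colon Adenocarcinoma	colon
Colorectal Adenocarcinoma	colon
Rectal Adenocarcinoma	colon
Esophageal Adenocarcinoma	esophagus
Esophagogastric Cancer	esophagus
Gallbladder Cancer	gallbladder
Cholangiocarcinoma	gallbladder
Head and Neck Squamous Cell Carcinoma	head_and_neck
Oral Cavity Cancer	head_and_neck
Renal Clear Cell Carcinoma	kidney
Renal Cell Carcinoma	kidney
Hepatocellular Carcinoma	liver
Lung Adenocarcinoma	lung
Lung Squamous Cell Carcinoma	lung
Non-Small Cell Lung Cancer	lung
Small Cell Lung Cancer	lung
Ovarian Epithelial Tumor	ovary
High-Grade Serous Ovarian Cancer	ovary
Pancreatic Adenocarcinoma	pancreas
Prostate Adenocarcinoma	prostate
Melanoma	skin
Cutaneous Melanoma	skin
Stomach Adenocarcinoma	stomach
Papillary Thyroid Cancer	thyroid
Anaplastic Thyroid Cancer	thyroid
Uterine Endometrioid Carcinoma	uterus
Endometrial Carcinoma	uterus
Lymph Node	lymph_node
Distant Lymph Node	lymph_node
Regional Lymph Node	lymph_node
Bone	bone
Bone Marrow	bone
Brain	brain
CNS/Brain	brain
Liver	liver
Lung	lung
Pleura	other
Adrenal Gland	other
Skin	skin
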